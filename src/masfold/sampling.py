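"""Restrained simulated annealing and minimization.

Dynamics are Cartesian velocity-Verlet with a per-step velocity-rescaling
thermostat. The integration timestep starts at 1 fs and is halved (down to
a 0.1 fs floor) whenever a step changes the total (potential + kinetic)
energy by more than a configured fraction, then gradually restored —
a simple surrogate for self-adjusting, energy-conserving stepping.

A rigid group (used in the neck-linker stage) moves with 6 degrees of
freedom: net force and torque about its center of mass drive translation
and exact-rotation updates, so internal geometry is preserved bitwise up
to the rotation itself.

Unit conventions: coordinates A, time fs, velocities A/fs, masses amu,
energies kcal/mol. Acceleration = force/mass * 4.184e-4 A/fs^2 per
(kcal/mol/A/amu); kinetic energy = 0.5 m v^2 * 2390.057 kcal/mol.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial.transform import Rotation

from .energy import KB, System, EnergyBreakdown

ACC = 4.184e-4            # (kcal/mol/A)/amu -> A/fs^2
KE_CONV = 1.0 / ACC       # amu (A/fs)^2 -> kcal/mol


# ---------------------------------------------------------------------------
# schedule

@dataclass
class CoolingSpec:
    t_start: float = 3000.0
    t_end: float = 25.0
    decrement: float = 25.0
    per_t_duration_ps: float = 0.4
    strict: bool = True   # False: allow a non-dividing decrement, ending at t_end

    def temperatures(self) -> np.ndarray:
        span = self.t_start - self.t_end
        n = span / self.decrement
        if self.t_end >= self.t_start:
            raise ValueError("t_end must be below t_start")
        if abs(n - round(n)) > 1e-9:
            if self.strict:
                raise ValueError("decrement must divide (t_start - t_end)")
            temps = self.t_start - self.decrement * np.arange(int(np.floor(n)) + 1)
            return np.append(temps, self.t_end)
        return self.t_start - self.decrement * np.arange(int(round(n)) + 1)


@dataclass
class AnnealingSchedule:
    """High-temperature stages, a cooling ladder, and force-constant ramps.

    `ramps` maps term names to (k_initial, k_final) interpolated linearly
    in cooling-stage index; `high_t_constants` fixes term force constants
    during the high-temperature stages (defaulting to the ramp's initial
    value).
    """

    high_t_stages: list = field(default_factory=lambda: [(3000.0, 10.0, 10000)] * 2)
    cooling: CoolingSpec | None = field(default_factory=CoolingSpec)
    ramps: dict = field(default_factory=lambda: {"distance": (2.0, 30.0),
                                                 "dihedral": (200.0, 200.0)})
    high_t_constants: dict = field(default_factory=lambda: {"dihedral": 10.0})
    constants: dict = field(default_factory=lambda: {"map": 50.0})
    initial_timestep_fs: float = 1.0

    def __post_init__(self):
        for T, dur, _steps in self.high_t_stages:
            if dur <= 0:
                raise ValueError("stage durations must be positive")
        if self.cooling is not None:
            self.cooling.temperatures()  # validate
            if self.cooling.per_t_duration_ps <= 0:
                raise ValueError("stage durations must be positive")

    def n_cooling_stages(self) -> int:
        return 0 if self.cooling is None else len(self.cooling.temperatures())

    def ramped_constants(self, stage_index: int) -> dict:
        """Force constants for cooling stage `stage_index` (0-based)."""
        n = self.n_cooling_stages()
        frac = stage_index / (n - 1) if n > 1 else 1.0
        out = {name: k0 + (k1 - k0) * frac for name, (k0, k1) in self.ramps.items()}
        out.update(self.constants)
        return out

    def high_t_constants_full(self) -> dict:
        out = {name: k0 for name, (k0, _k1) in self.ramps.items()}
        out.update(self.constants)
        out.update(self.high_t_constants)
        return out


def build_schedule(config: dict | None = None) -> AnnealingSchedule:
    """Build an annealing schedule from a configuration mapping.

    The default reproduces the production protocol: two 3000 K stages
    (10 ps or 10,000 steps, whichever completes first), cooling from
    3000 K to 25 K in 25 K steps with 0.4 ps per temperature, distance
    force constant ramped 2 -> 30 kcal/mol/A^2, dihedral constant
    10 kcal/mol/rad^2 at high temperature and 200 during cooling, and a
    constant map force constant of 50 kcal/mol.
    """
    cfg = dict(config or {})
    cooling_cfg = cfg.pop("cooling", {})
    cooling = None if cooling_cfg is None else CoolingSpec(**cooling_cfg)
    kwargs = {}
    for key in ("high_t_stages", "ramps", "high_t_constants", "constants",
                "initial_timestep_fs"):
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if cfg:
        raise ValueError(f"unknown schedule config keys: {sorted(cfg)}")
    if "high_t_stages" in kwargs:
        kwargs["high_t_stages"] = [tuple(s) for s in kwargs["high_t_stages"]]
    return AnnealingSchedule(cooling=cooling, **kwargs)


# ---------------------------------------------------------------------------
# velocities

def maxwell_velocities(masses_or_structure, temperature: float,
                       seed: int) -> np.ndarray:
    """Per-component Gaussian velocities (A/fs) at the target temperature."""
    masses = getattr(masses_or_structure, "masses", masses_or_structure)
    masses = np.asarray(masses, float)
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if temperature == 0:
        return np.zeros((len(masses), 3))
    rng = np.random.default_rng(seed)
    std = np.sqrt(KB * temperature / (masses * KE_CONV))
    return rng.normal(size=(len(masses), 3)) * std[:, None]


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    return 0.5 * KE_CONV * float(np.sum(masses[:, None] * velocities ** 2))


def measured_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    ke = kinetic_energy(masses, velocities)
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * KB)


# ---------------------------------------------------------------------------
# rigid groups

class _RigidState:
    """Center-of-mass velocity and angular velocity of one rigid group."""

    def __init__(self, idx: np.ndarray, masses: np.ndarray):
        self.idx = idx
        self.m = masses[idx]
        self.mass = float(self.m.sum())
        self.v = np.zeros(3)
        self.omega = np.zeros(3)   # rad/fs

    def com(self, coords):
        return (self.m[:, None] * coords[self.idx]).sum(axis=0) / self.mass

    def inertia(self, coords):
        rel = coords[self.idx] - self.com(coords)
        r2 = np.sum(rel ** 2, axis=1)
        I = np.einsum("a,ab,ac->bc", self.m, rel, rel)
        return np.diag((self.m * r2).sum() * np.ones(3)) - I

    def kinetic(self, coords):
        I = self.inertia(coords)
        return 0.5 * KE_CONV * (self.mass * self.v @ self.v
                                + self.omega @ I @ self.omega)

    def step(self, coords, forces, dt):
        com = self.com(coords)
        F = forces[self.idx].sum(axis=0)
        rel = coords[self.idx] - com
        tau = np.cross(rel, forces[self.idx]).sum(axis=0)
        I = self.inertia(coords)
        self.v = self.v + dt * F / self.mass * ACC
        self.omega = self.omega + dt * np.linalg.solve(
            I + 1e-9 * np.eye(3), tau) * ACC
        R = Rotation.from_rotvec(self.omega * dt).as_matrix()
        coords[self.idx] = rel @ R.T + com + self.v * dt

    def rescale(self, factor):
        self.v *= factor
        self.omega *= factor


# ---------------------------------------------------------------------------
# dynamics

@dataclass
class StageLog:
    temperature: float
    steps: int
    final_potential: float
    final_kinetic: float
    measured_temperature: float
    timestep_adjustments: int
    final_timestep_fs: float
    failed: bool = False


class DynamicsFailure(RuntimeError):
    def __init__(self, msg, coords, velocities, log):
        super().__init__(msg)
        self.coords, self.velocities, self.log = coords, velocities, log


def dynamics_stage(system: System, coords: np.ndarray, velocities: np.ndarray,
                   temperature: float, duration_ps: float,
                   timestep_fs: float = 1.0, max_steps: int | None = None,
                   thermostat: bool = True, econs_tol: float = 0.02,
                   min_timestep_fs: float = 0.1,
                   rigid_states: list[_RigidState] | None = None):
    """One thermostatted velocity-Verlet stage with adaptive timestep.

    Returns (coords, velocities, StageLog). The timestep halves whenever a
    step changes total energy by more than `econs_tol` (relative, with a
    small absolute floor) and is gradually restored toward `timestep_fs`.
    """
    masses = system.masses
    rigid_states = rigid_states or []
    rigid_atoms = (np.concatenate([r.idx for r in rigid_states])
                   if rigid_states else np.array([], int))
    free = np.setdiff1d(np.arange(len(coords)), rigid_atoms)
    ndof = 3 * len(free) + 6 * len(rigid_states)

    def total_ke(x, v):
        ke = 0.5 * KE_CONV * float(np.sum(masses[free, None] * v[free] ** 2))
        for r in rigid_states:
            ke += r.kinetic(x)
        return ke

    def temp(x, v):
        return 2.0 * total_ke(x, v) / (max(ndof, 1) * KB)

    x = coords.copy()
    v = velocities.copy()
    dt = float(timestep_fs)
    bd = system.energy(x)
    if not np.isfinite(bd.total):
        raise ValueError("non-finite starting energy")
    pe, grad = bd.total, bd.gradient
    t_sim = 0.0
    duration_fs = duration_ps * 1000.0
    steps = 0
    adjustments = 0
    failed = False
    cap = max_steps if max_steps is not None else int(duration_fs / min_timestep_fs) + 1
    while t_sim < duration_fs - 1e-9 and steps < cap:
        forces = -grad
        e_before = pe + total_ke(x, v)
        x_new = x.copy()
        v_new = v.copy()
        # free atoms: velocity Verlet half-kick / drift
        a = forces[free] / masses[free, None] * ACC
        v_half = v[free] + 0.5 * dt * a
        x_new[free] = x[free] + dt * v_half
        # rigid groups: force/torque integration with exact rotations
        new_rigid = [copy.deepcopy(r) for r in rigid_states]
        for r in new_rigid:
            r.step(x_new, forces, dt)
        bd_new = system.energy(x_new)
        pe_new, grad_new = bd_new.total, bd_new.gradient
        a_new = -grad_new[free] / masses[free, None] * ACC
        v_new[free] = v_half + 0.5 * dt * a_new
        e_after = pe_new + total_ke(x_new, v_new)
        tol = econs_tol * max(abs(e_before), 10.0)
        if not np.isfinite(e_after) or abs(e_after - e_before) > tol:
            if dt <= min_timestep_fs + 1e-12:
                failed = True
                break
            dt = max(dt * 0.5, min_timestep_fs)
            adjustments += 1
            continue
        x, v, pe, grad = x_new, v_new, pe_new, grad_new
        rigid_states[:] = new_rigid
        t_sim += dt
        steps += 1
        if dt < timestep_fs:
            dt = min(dt * 1.25, timestep_fs)
        if thermostat:
            t_now = temp(x, v)
            if t_now > 1e-12:
                factor = np.sqrt(temperature / t_now)
                v[free] *= factor
                for r in rigid_states:
                    r.rescale(factor)
    log = StageLog(temperature, steps, pe, total_ke(x, v), temp(x, v),
                   adjustments, dt, failed)
    return x, v, log


# ---------------------------------------------------------------------------
# minimization

def minimize(system: System, coords: np.ndarray | None = None,
             max_iter: int = 500, gtol: float = 1e-3,
             movable: np.ndarray | None = None):
    """Gradient-based Cartesian minimization (L-BFGS-B).

    `movable` restricts optimization to a subset of atoms (rigid regions
    stay fixed). Returns (coords, EnergyBreakdown). Final energy never
    exceeds the starting energy.
    """
    x0 = (system.structure.coords if coords is None else coords).copy()
    if not np.isfinite(system.energy(x0, with_gradient=False).total):
        raise ValueError("non-finite starting energy")
    mov = np.arange(len(x0)) if movable is None else np.asarray(movable, int)
    if len(mov) == 0:
        return x0, system.energy(x0)

    def fun(p):
        x = x0.copy()
        x[mov] = p.reshape(-1, 3)
        bd = system.energy(x)
        return bd.total, bd.gradient[mov].ravel()

    res = optimize.minimize(fun, x0[mov].ravel(), jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "gtol": gtol,
                                     "maxls": 50})
    e_start = system.energy(x0, with_gradient=False).total
    x_final = x0.copy()
    if res.fun <= e_start:
        x_final[mov] = res.x.reshape(-1, 3)
    return x_final, system.energy(x_final)


def _relax_added_atoms(structure, added_idx, repulsion: bool = False,
                       max_iter: int = 300) -> None:
    """Covalent-only relaxation of newly built atoms (used by extend_chain)."""
    from .energy import CovalentTerm, EnergyTerm

    class _SoftRepulsion(EnergyTerm):
        name = "repulsion"

        def __init__(self, idx_a, idx_b, rmin=2.2, k=10.0):
            super().__init__(k=k)
            self.idx_a, self.idx_b, self.rmin = idx_a, idx_b, rmin

        def evaluate(self, coords, grad=None):
            diff = coords[self.idx_a][:, None, :] - coords[self.idx_b][None, :, :]
            d = np.maximum(np.linalg.norm(diff, axis=2), 1e-6)
            pen = np.maximum(self.rmin - d, 0.0)
            e = self.k * float(np.sum(pen ** 2))
            if grad is not None and pen.any():
                coeff = -2.0 * self.k * pen / d
                g = coeff[..., None] * diff
                np.add.at(grad, self.idx_a, g.sum(axis=1))
                np.add.at(grad, self.idx_b, -g.sum(axis=0))
            return e

    terms = [CovalentTerm(structure.topology)]
    if repulsion:
        other = np.setdiff1d(np.arange(structure.n_atoms), added_idx)
        terms.append(_SoftRepulsion(np.asarray(added_idx, int), other))
    system = System(structure, terms)
    coords, _ = minimize(system, structure.coords, max_iter=max_iter,
                         movable=np.asarray(added_idx, int))
    structure.coords = coords


# ---------------------------------------------------------------------------
# annealing

@dataclass
class RunResult:
    structure: object            # final Structure (or Assembly-shaped Structure)
    breakdown: EnergyBreakdown
    seed: int
    stage_logs: list = field(default_factory=list)
    failed: bool = False

    @property
    def energy(self) -> float:
        return self.breakdown.total


def _set_constants(system: System, constants: dict) -> None:
    for name, k in constants.items():
        try:
            system.term(name).k = float(k)
        except KeyError:
            pass


def anneal(system: System, schedule: AnnealingSchedule, seed: int,
           minimize_after: bool = True) -> RunResult:
    """High-temperature dynamics, cooling with ramped force constants, then
    minimization. Fully determined by (system, schedule, seed)."""
    coords = system.structure.coords.copy()
    masses = system.masses
    rigid_states = [_RigidState(g, masses) for g in system.rigid_groups]
    logs = []
    failed = False

    stages = schedule.high_t_stages
    if stages:
        t0 = stages[0][0]
    else:
        t0 = schedule.cooling.t_start if schedule.cooling is not None else 0.0
    velocities = maxwell_velocities(masses, t0, seed)
    for g in system.rigid_groups:
        velocities[g] = 0.0

    _set_constants(system, schedule.high_t_constants_full())
    for (T, dur, max_steps) in stages:
        coords, velocities, log = dynamics_stage(
            system, coords, velocities, T, dur, schedule.initial_timestep_fs,
            max_steps=max_steps, rigid_states=rigid_states)
        logs.append(log)
        failed |= log.failed

    cooling_temps = (schedule.cooling.temperatures()
                     if schedule.cooling is not None else [])
    for i, T in enumerate(cooling_temps):
        _set_constants(system, schedule.ramped_constants(i))
        coords, velocities, log = dynamics_stage(
            system, coords, velocities, T, schedule.cooling.per_t_duration_ps,
            schedule.initial_timestep_fs, rigid_states=rigid_states)
        logs.append(log)
        failed |= log.failed

    movable = None
    if system.rigid_groups:
        rigid_atoms = np.concatenate(system.rigid_groups)
        movable = np.setdiff1d(np.arange(len(coords)), rigid_atoms)
    if minimize_after:
        coords, breakdown = minimize(system, coords, movable=movable)
    else:
        breakdown = system.energy(coords)

    final = system.structure.copy()
    final.coords = coords
    if hasattr(system.model, "set_coords"):
        pass  # callers relying on the Assembly view use RunResult.structure
    return RunResult(final, breakdown, seed, logs, failed)


def stage_logs_to_tsv(result: "RunResult", path) -> None:
    """Per-run log: one row per dynamics stage (temperature, steps, energies,
    timestep adjustments)."""
    import pandas as pd
    rows = [{"stage": i, "temperature_K": log.temperature, "steps": log.steps,
             "potential_kcal_mol": log.final_potential,
             "kinetic_kcal_mol": log.final_kinetic,
             "measured_T_K": log.measured_temperature,
             "timestep_adjustments": log.timestep_adjustments,
             "final_timestep_fs": log.final_timestep_fs,
             "failed": log.failed}
            for i, log in enumerate(result.stage_logs)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


def run_batch(system_factory, n_structures: int, base_seed: int,
              schedule: AnnealingSchedule | None = None) -> list[RunResult]:
    """n independent seeded annealing runs, sorted ascending by final energy.

    `system_factory` is called once per run and may return a System or a
    (System, AnnealingSchedule) pair; failures are excluded and counted.
    """
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    results, n_failed = [], 0
    for i in range(n_structures):
        made = system_factory()
        if isinstance(made, tuple):
            system, sched = made
        else:
            system, sched = made, schedule
        if sched is None:
            sched = AnnealingSchedule()
        try:
            res = anneal(system, sched, base_seed + i)
        except (ValueError, FloatingPointError):
            n_failed += 1
            continue
        if res.failed:
            n_failed += 1
            continue
        results.append(res)
    if n_failed:
        import warnings
        warnings.warn(f"{n_failed} of {n_structures} runs failed and were excluded")
    results.sort(key=lambda r: r.energy)
    return results
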