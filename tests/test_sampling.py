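"""Annealing schedules, velocities, dynamics, minimization and batches."""

import numpy as np
import pytest

import masfold as mf
from masfold.energy import CovalentTerm, DistanceRestraintTerm, System
from masfold.sampling import (AnnealingSchedule, CoolingSpec, dynamics_stage,
                              kinetic_energy, measured_temperature)


def harmonic_dimer(k=300.0, r0=1.5):
    st = mf.Structure(["A", "A"], [1, 1], ["GLY", "GLY"], ["CA", "C"],
                      ["C", "C"], np.array([[0.0, 0, 0], [r0, 0, 0]]))
    from masfold.structure import Topology
    st.topology = Topology(np.array([[0, 1]]), np.array([r0]),
                           np.empty((0, 3), int), np.empty(0),
                           np.empty((0, 4), int), np.empty(0),
                           {"bond": k})
    return st


class TestSchedule:
    def test_default_matches_protocol(self):
        s = mf.build_schedule()
        assert s.n_cooling_stages() == 120
        assert len(s.high_t_stages) == 2
        assert s.high_t_stages[0] == (3000.0, 10.0, 10000)
        assert s.ramped_constants(0)["distance"] == 2.0
        assert s.ramped_constants(119)["distance"] == 30.0
        assert s.high_t_constants_full()["dihedral"] == 10.0
        assert s.ramped_constants(0)["dihedral"] == 200.0
        assert s.ramped_constants(60)["map"] == 50.0
        assert s.initial_timestep_fs == 1.0

    def test_decrement_must_divide(self):
        with pytest.raises(ValueError):
            mf.build_schedule({"cooling": {"decrement": 111.0}})

    def test_non_strict_ladder_ends_at_t_end(self):
        spec = CoolingSpec(3000.0, 25.0, 125.0, 0.4, strict=False)
        temps = spec.temperatures()
        assert temps[0] == 3000.0 and temps[-1] == 25.0
        assert np.all(np.diff(temps) < 0)

    def test_ramp_endpoints_exact(self):
        s = mf.build_schedule({"cooling": {"decrement": 425.0,
                                           "per_t_duration_ps": 0.1},
                               "ramps": {"distance": (2.0, 30.0)}})
        n = s.n_cooling_stages()
        assert s.ramped_constants(0)["distance"] == 2.0
        assert s.ramped_constants(n - 1)["distance"] == 30.0

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            mf.build_schedule({"bogus": 1})


class TestMaxwell:
    def test_deterministic(self):
        masses = np.full(100, 12.011)
        v1 = mf.maxwell_velocities(masses, 3000.0, seed=4)
        v2 = mf.maxwell_velocities(masses, 3000.0, seed=4)
        assert np.array_equal(v1, v2)

    def test_zero_temperature(self):
        v = mf.maxwell_velocities(np.full(10, 12.0), 0.0, seed=1)
        assert np.all(v == 0.0)

    def test_equipartition_large_system(self):
        masses = np.full(10_000, 12.011)
        v = mf.maxwell_velocities(masses, 3000.0, seed=2)
        assert measured_temperature(masses, v) == pytest.approx(3000.0, abs=150.0)


class TestDynamics:
    def test_zero_force_linear_drift(self):
        st = harmonic_dimer()
        st.topology.bonds = np.empty((0, 2), int)
        st.topology.bond_ideal = np.empty(0)
        system = System(st, [])
        v0 = np.array([[0.01, 0.0, 0.0], [0.0, 0.01, 0.0]])
        coords, v, log = dynamics_stage(system, st.coords, v0, 300.0, 0.1,
                                        timestep_fs=1.0, thermostat=False)
        expected = st.coords + v0 * log.steps * 1.0
        assert np.allclose(coords, expected, atol=1e-9)
        assert log.final_potential == 0.0

    def test_harmonic_dimer_energy_conservation(self):
        st = harmonic_dimer()
        system = System(st, [CovalentTerm(st.topology)])
        coords = st.coords.copy()
        coords[1, 0] += 0.1  # stretch
        v = np.zeros((2, 3))
        e0 = system.energy(coords, with_gradient=False).total
        out, v_out, log = dynamics_stage(system, coords, v, 300.0, 10.0,
                                         timestep_fs=1.0, thermostat=False)
        e1 = system.energy(out, with_gradient=False).total + \
            kinetic_energy(st.masses, v_out)
        assert e1 == pytest.approx(e0, rel=0.01)
        assert not log.failed

    def test_deterministic_trajectory(self, toy_fold, fixture_restraints):
        term = DistanceRestraintTerm(fixture_restraints, toy_fold, k=10.0)
        cov = CovalentTerm(toy_fold.topology)

        def run():
            system = System(toy_fold.copy(), [term, cov])
            v = mf.maxwell_velocities(system.masses, 500.0, seed=9)
            return dynamics_stage(system, toy_fold.coords.copy(), v, 500.0,
                                  0.05, 1.0)
        c1, v1, l1 = run()
        c2, v2, l2 = run()
        assert np.array_equal(c1, c2)
        assert np.array_equal(v1, v2)
        assert l1 == l2

    def test_thermostat_tracks_target(self, toy_fold, fixture_restraints):
        system = System(toy_fold.copy(),
                        [DistanceRestraintTerm(fixture_restraints, toy_fold, 10.0),
                         CovalentTerm(toy_fold.topology)])
        v = mf.maxwell_velocities(system.masses, 1000.0, seed=3)
        coords, v, log = dynamics_stage(system, toy_fold.coords.copy(), v,
                                        1000.0, 0.1, 1.0)
        assert log.measured_temperature == pytest.approx(1000.0, rel=0.1)


class TestMinimize:
    def test_at_minimum_unchanged(self, toy_fold):
        system = System(toy_fold, [CovalentTerm(toy_fold.topology)])
        coords, bd = mf.minimize(system)
        assert np.allclose(coords, toy_fold.coords, atol=1e-6)
        assert bd.total == pytest.approx(0.0, abs=1e-9)

    def test_stretched_bond_relaxes(self):
        st = harmonic_dimer()
        system = System(st, [CovalentTerm(st.topology)])
        coords = st.coords.copy()
        coords[1, 0] = 2.0
        out, bd = mf.minimize(system, coords)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(1.5, abs=1e-3)

    def test_energy_never_increases(self, toy_fold, rng):
        system = System(toy_fold, [CovalentTerm(toy_fold.topology)])
        coords = toy_fold.coords + rng.normal(0, 0.2, toy_fold.coords.shape)
        e0 = system.energy(coords, with_gradient=False).total
        _, bd = mf.minimize(system, coords)
        assert bd.total <= e0

    def test_nonfinite_start_rejected(self, toy_fold):
        system = System(toy_fold, [CovalentTerm(toy_fold.topology)])
        coords = toy_fold.coords.copy()
        coords[0, 0] = np.nan
        with pytest.raises(ValueError):
            mf.minimize(system, coords)


class TestAnneal:
    def _system(self, fixture_a, fixture_restraints, start_noise=0.8, seed=0):
        st = fixture_a["structure"].copy()
        st.coords = st.coords + np.random.default_rng(seed).normal(
            0, start_noise, st.coords.shape)
        terms = [DistanceRestraintTerm(fixture_restraints, st, k=2.0),
                 mf.TorsionRestraintTerm(fixture_a["torsions"], st, k=10.0),
                 CovalentTerm(st.topology)]
        return System(st, terms)

    def test_restraint_energy_drops(self, fixture_a, fixture_restraints,
                                    short_schedule):
        system = self._system(fixture_a, fixture_restraints, start_noise=1.0)
        e0 = system.energy(with_gradient=False).terms["distance"]
        # evaluated at the production force constant for comparability
        system.term("distance").k = 30.0
        e0 = system.energy(with_gradient=False).terms["distance"]
        res = mf.anneal(system, short_schedule, seed=5)
        e1 = res.breakdown.terms["distance"]
        assert e0 > 0
        assert e1 < 0.1 * e0

    def test_zero_stage_schedule_is_minimize_only(self, fixture_a,
                                                  fixture_restraints):
        system = self._system(fixture_a, fixture_restraints, start_noise=0.05)
        sched = AnnealingSchedule(high_t_stages=[], cooling=None)
        res = mf.anneal(system, sched, seed=1)
        e0 = system.energy(with_gradient=False).total
        assert res.energy <= e0
        assert res.stage_logs == []

    def test_two_seeds_differ_but_satisfy(self, fixture_a, fixture_restraints,
                                          short_schedule):
        sys_a = self._system(fixture_a, fixture_restraints, 0.8)
        sys_b = self._system(fixture_a, fixture_restraints, 0.8)
        ra = mf.anneal(sys_a, short_schedule, seed=1)
        rb = mf.anneal(sys_b, short_schedule, seed=2)
        assert not np.allclose(ra.structure.coords, rb.structure.coords)
        for res, system in ((ra, sys_a), (rb, sys_b)):
            term = system.term("distance")
            viols = term.violations(res.structure.coords)
            unamb = np.bincount(term.rid).searchsorted(2)  # all here are per-restraint
            assert np.abs(viols).max() <= 0.5

    def test_breakdown_consistent_with_energy_module(self, fixture_a,
                                                     fixture_restraints,
                                                     short_schedule):
        system = self._system(fixture_a, fixture_restraints, 0.5)
        res = mf.anneal(system, short_schedule, seed=7)
        again = system.energy(res.structure.coords, with_gradient=False)
        assert res.breakdown.total == pytest.approx(again.total, rel=1e-9)


class TestRunLogs:
    def test_stage_log_tsv(self, fixture_a, fixture_restraints, short_schedule,
                           tmp_path):
        import pandas as pd
        st = fixture_a["structure"]
        system = System(st.copy(),
                        [DistanceRestraintTerm(fixture_restraints, st, 2.0),
                         CovalentTerm(st.topology)])
        res = mf.anneal(system, short_schedule, seed=0)
        path = tmp_path / "run.tsv"
        mf.stage_logs_to_tsv(res, path)
        df = pd.read_csv(path, sep="\t")
        n_stages = len(short_schedule.high_t_stages) + \
            short_schedule.n_cooling_stages()
        assert len(df) == n_stages
        assert set(df.columns) >= {"temperature_K", "steps",
                                   "potential_kcal_mol"}


class TestRunBatch:
    def test_singleton(self, fixture_a, fixture_restraints, short_schedule):
        st = fixture_a["structure"]
        factory = lambda: System(
            st.copy(), [DistanceRestraintTerm(fixture_restraints, st, 2.0),
                        CovalentTerm(st.topology)])
        results = mf.run_batch(factory, 1, base_seed=3, schedule=short_schedule)
        assert len(results) == 1

    def test_sorted_by_energy(self, fixture_a, fixture_restraints,
                              short_schedule):
        st = fixture_a["structure"].copy()
        st.coords = st.coords + np.random.default_rng(1).normal(
            0, 0.8, st.coords.shape)
        factory = lambda: System(
            st.copy(), [DistanceRestraintTerm(fixture_restraints, st, 2.0),
                        mf.TorsionRestraintTerm(fixture_a["torsions"], st, 10.0),
                        CovalentTerm(st.topology)])
        results = mf.run_batch(factory, 4, base_seed=0, schedule=short_schedule)
        energies = [r.energy for r in results]
        assert energies == sorted(energies)
        assert {r.seed for r in results} == {0, 1, 2, 3}

    def test_lowest_energy_recovers_truth(self, fixture_a, fixture_restraints,
                                          short_schedule):
        """Scaled-down batch: the lowest-energy structure lands near the
        planted fold."""
        truth = fixture_a["structure"]
        start = truth.copy()
        start.coords = truth.coords + np.random.default_rng(8).normal(
            0, 0.6, truth.coords.shape)
        env = mf.simulate_map(start, 8.0, 2.0)

        def factory():
            st = start.copy()
            return System(st, [
                DistanceRestraintTerm(fixture_restraints, st, 2.0),
                mf.TorsionRestraintTerm(fixture_a["torsions"], st, 10.0),
                CovalentTerm(st.topology),
                mf.MapCCTerm(env, st.select("backbone"), k=50.0)])

        results = mf.run_batch(factory, 5, base_seed=0, schedule=short_schedule)
        best = results[0].structure
        rmsd = mf.superpose(truth, best, "backbone and name N,CA,C").rmsd
        assert rmsd < 1.5
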