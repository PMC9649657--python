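"""The four-stage structure-determination protocol and validation.

Stage 1: restrained simulated annealing of a single chain inside a blurred
envelope map. Stage 2: multi-position rigid-body docking of the lowest-energy
chain into the experimental map. Stage 3: joint refinement of all docked
copies with NCS similarity restraints and the map. Stage 4: localized
refinement of the mobile tail (neck linker) with the core held as one rigid
body, followed by realignment and a local density refit. Validation computes
restraint-violation and ensemble-precision statistics from the final
ensemble and the restraints alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import DensityMap, Placement, dock_positions, local_fit, simulate_map
from .energy import (CovalentTerm, DistanceRestraintTerm, MapCCTerm, NCSTerm,
                     System, TorsionRestraintTerm)
from .restraints import RestraintSummary, summarize_restraints
from .sampling import AnnealingSchedule, RunResult, anneal, build_schedule, run_batch
from .structure import (Assembly, Structure, geometry_deviations,
                        pairwise_ensemble_rmsd, replicate_subunits, superpose)


@dataclass
class PipelineConfig:
    """Stage toggles and parameters; defaults are the production protocol."""

    n_structures: int = 100          # stage-1 (and stage-3) annealed structures
    n_structures_stage3: int | None = None
    n_subunits: int = 22
    free_range: tuple = (321, 349)   # residues free in stage 4
    n_per_subunit: int = 1000        # stage-4 structures per subunit
    envelope_resolution: float = 8.0
    voxel_size: float = 2.0
    map_selection: str = "backbone"  # atoms carrying the map term
    map_residue_mask: str | None = None  # e.g. "resi 3-6,8-167,169-173,175-320"
    k_map: float = 50.0
    ncs_tolerance: float = 1.0
    k_ncs: float = 50.0
    rotation_samples: int = 2000
    min_separation: float | None = None
    dock_kwargs: dict = field(default_factory=dict)
    schedule: AnnealingSchedule | dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        lo, hi = self.free_range
        if lo > hi or lo < 1:
            raise ValueError("free_range must be a valid 1-based residue range")

    def get_schedule(self) -> AnnealingSchedule:
        if isinstance(self.schedule, AnnealingSchedule):
            return self.schedule
        return build_schedule(self.schedule)


def _map_atom_indices(structure: Structure, config: PipelineConfig) -> np.ndarray:
    expr = config.map_selection
    if config.map_residue_mask:
        expr = f"{expr} and {config.map_residue_mask}"
    return structure.select(expr)


def _single_chain_system(structure: Structure, restraints, torsions,
                         dmap: DensityMap | None, config: PipelineConfig,
                         rigid_groups=None) -> System:
    st = structure.copy()
    if st.topology is None or st.topology.empty:
        from .structure import build_topology
        build_topology(st)
    terms = [
        DistanceRestraintTerm(restraints, st, k=2.0),
        TorsionRestraintTerm(torsions, st, k=10.0),
        CovalentTerm(st.topology),
    ]
    if dmap is not None:
        terms.append(MapCCTerm(dmap, _map_atom_indices(st, config), k=config.k_map))
    return System(st, terms, rigid_groups=rigid_groups)


# ---------------------------------------------------------------------------
# stage 1

def stage1_single_chain(start_structure: Structure, restraints, torsions,
                        envelope_map: DensityMap | None = None,
                        config: PipelineConfig | None = None):
    """Anneal a batch of single chains; return (lowest-energy chain, results).

    Without an explicit envelope, a synthetic one is simulated from the
    start coordinates at the configured envelope resolution to preserve the
    overall shape during annealing.
    """
    config = config or PipelineConfig()
    if envelope_map is None:
        envelope_map = simulate_map(start_structure, config.envelope_resolution,
                                    config.voxel_size)
    schedule = config.get_schedule()

    def factory():
        return _single_chain_system(start_structure, restraints, torsions,
                                    envelope_map, config)

    results = run_batch(factory, config.n_structures, config.seed, schedule)
    if not results:
        raise RuntimeError("all stage-1 annealing runs failed")
    return results[0].structure, results


# ---------------------------------------------------------------------------
# stage 2

def stage2_dock(chain: Structure, experimental_map: DensityMap,
                n: int | None = None, config: PipelineConfig | None = None,
                out_dir=None):
    """Dock the chain at multiple positions; placements sorted by CC.

    With `out_dir`, a score table (placements.tsv) and the transformed
    chain copies (placed_XX.pdb) are written there.
    """
    config = config or PipelineConfig()
    n = n if n is not None else config.n_subunits
    placements = dock_positions(
        chain, experimental_map, n,
        rotation_samples=config.rotation_samples,
        min_separation=config.min_separation, **config.dock_kwargs)
    if len(placements) < n:
        warnings.warn(f"proceeding with {len(placements)} of {n} placements")
    if out_dir is not None:
        from pathlib import Path
        from .density import placements_to_tsv
        from .structure import write_structure
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        placements_to_tsv(placements, out / "placements.tsv")
        for k, pl in enumerate(placements):
            copy = chain.copy()
            copy.coords = pl.apply(chain.coords)
            write_structure(copy, out / f"placed_{k:02d}.pdb")
    return placements


# ---------------------------------------------------------------------------
# stage 3

def _assembly_system(chain: Structure, placements, restraints, torsions,
                     experimental_map, config: PipelineConfig):
    n = len(placements)
    assembly = replicate_subunits(chain, n)
    for sub, pl in zip(assembly.subunits, placements):
        sub.coords = pl.apply(chain.coords)
    combined = assembly.to_structure()
    n_per = chain.n_atoms
    terms = []
    for k in range(n):
        terms.append(DistanceRestraintTerm(restraints, chain, k=2.0,
                                           index_offset=k * n_per))
        terms.append(TorsionRestraintTerm(torsions, chain, k=10.0,
                                          index_offset=k * n_per))
    # merge per-subunit restraint terms into two vectorized terms
    dist = _merge_distance_terms([t for t in terms if t.name == "distance"])
    dih = _merge_torsion_terms([t for t in terms if t.name == "dihedral"])
    groups = [np.arange(k * n_per, (k + 1) * n_per) for k in range(n)]
    sys_terms = [dist, dih, CovalentTerm(combined.topology),
                 NCSTerm(groups, tolerance=config.ncs_tolerance, k=config.k_ncs)]
    if experimental_map is not None:
        sys_terms.append(MapCCTerm(experimental_map,
                                   _map_atom_indices(combined, config),
                                   k=config.k_map))
    system = System(combined, sys_terms)
    return system, assembly


def _merge_distance_terms(terms):
    base = terms[0]
    if len(terms) == 1:
        return base
    pair_i = np.concatenate([t.pair_i for t in terms])
    pair_j = np.concatenate([t.pair_j for t in terms])
    rid, lower, upper, off = [], [], [], 0
    for t in terms:
        rid.append(t.rid + off)
        lower.append(t.lower)
        upper.append(t.upper)
        off += t.n_restraints
    return DistanceRestraintTerm.from_arrays(
        pair_i, pair_j, np.concatenate(rid), np.concatenate(lower),
        np.concatenate(upper), k=base.k)


def _merge_torsion_terms(terms):
    if len(terms) == 1:
        return terms[0]
    return TorsionRestraintTerm.from_arrays(
        np.concatenate([t.quads for t in terms]),
        np.concatenate([t.targets for t in terms]),
        np.concatenate([t.tols for t in terms]), k=terms[0].k)


def stage3_joint_refine(chain: Structure, placements, restraints, torsions,
                        experimental_map: DensityMap | None,
                        config: PipelineConfig | None = None):
    """NCS-restrained joint refinement of all placed copies.

    Every subunit carries the full single-chain restraint set; an NCS term
    keeps pairwise subunit RMSDs within the tolerance, and the map term acts
    on the whole assembly. Returns (refined Assembly, best RunResult).
    """
    config = config or PipelineConfig()
    if chain.topology is None or chain.topology.empty:
        from .structure import build_topology
        build_topology(chain)
    schedule = config.get_schedule()
    n_runs = config.n_structures_stage3 or config.n_structures

    def factory():
        system, _ = _assembly_system(chain, placements, restraints, torsions,
                                     experimental_map, config)
        return system

    results = run_batch(factory, n_runs, config.seed + 10_000, schedule)
    if not results:
        raise RuntimeError("all stage-3 refinement runs failed")
    best = results[0]
    assembly = replicate_subunits(chain, len(placements))
    assembly.set_coords(best.structure.coords)
    return assembly, best


# ---------------------------------------------------------------------------
# stage 4

def stage4_neck_linker(assembly: Assembly, extra_restraints, restraints,
                       torsions, experimental_map: DensityMap | None = None,
                       free_range: tuple | None = None,
                       n_per_subunit: int | None = None,
                       config: PipelineConfig | None = None):
    """Per-subunit localized refinement of the mobile tail.

    Residues outside `free_range` move only as one rigid body during
    dynamics (and stay fixed in the final minimization); the tail and any
    extra restraints drive its conformation. Each refined conformer is
    realigned onto its stage-3 pose via the core backbone and, when a map
    is available, locally refit to the density. Returns the final Assembly.
    """
    config = config or PipelineConfig()
    free_range = free_range or config.free_range
    n_runs = n_per_subunit or config.n_per_subunit
    all_restraints = list(restraints) + list(extra_restraints)
    lo, hi = free_range
    final_subunits = []
    for k, sub in enumerate(assembly.subunits):
        free_idx = sub.select(f"resi {lo}-{hi}")
        if len(free_idx) == 0:
            raise ValueError("free_range selects no atoms")
        rigid_idx = np.setdiff1d(np.arange(sub.n_atoms), free_idx)

        def factory(sub=sub, rigid_idx=rigid_idx):
            return _single_chain_system(sub, all_restraints, torsions,
                                        experimental_map, config,
                                        rigid_groups=[rigid_idx])

        results = run_batch(factory, n_runs, config.seed + 20_000 + 1000 * k,
                            config.get_schedule())
        if not results:
            raise RuntimeError(f"all stage-4 runs failed for subunit {k}")
        best = results[0].structure
        # realign the conformer onto its stage-3 pose via the core backbone
        core = f"backbone and resi {sub.res_indices.min()}-{lo - 1}"
        sup = superpose(sub, best, core)
        best = best.copy()
        best.coords = sup.apply(best.coords)
        if experimental_map is not None:
            pl = local_fit(best, experimental_map, Placement.identity(),
                           maxfev=config.dock_kwargs.get("maxfev", 250))
            best.coords = pl.apply(best.coords)
        final_subunits.append(best)
    return Assembly(final_subunits, list(assembly.segment_ids))


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    restraint_summary: RestraintSummary
    distance_violation_mean: float
    distance_violation_sd: float
    max_distance_violation: float
    dihedral_violation_mean: float
    dihedral_violation_sd: float
    max_dihedral_violation: float
    bond_rmsd_mean: float
    bond_rmsd_sd: float
    angle_rmsd_mean: float
    angle_rmsd_sd: float
    improper_rmsd_mean: float
    improper_rmsd_sd: float
    rmsd_backbone_mean: float = np.nan
    rmsd_backbone_sd: float = np.nan
    rmsd_heavy_mean: float = np.nan
    rmsd_heavy_sd: float = np.nan
    per_stage_energies: dict = field(default_factory=dict)

    def to_text(self) -> str:
        s = self.restraint_summary
        lines = [
            "Restraints",
            f"  unambiguous {s.unambiguous} (intra {s.intra}, inter {s.inter}: "
            f"seq {s.sequential}, medium {s.medium}, long {s.long})",
            f"  ambiguous {s.ambiguous}, total {s.total} "
            f"({s.restraints_per_residue}/residue)",
            f"  torsions: {s.phi} phi + {s.psi} psi = {s.torsion_total}",
            "Violations (mean +/- sd over conformers)",
            f"  distance beyond upper bound (A): {self.distance_violation_mean:.3f}"
            f" +/- {self.distance_violation_sd:.3f}",
            f"  dihedral beyond tolerance (deg): {self.dihedral_violation_mean:.3f}"
            f" +/- {self.dihedral_violation_sd:.3f}",
            f"  max distance violation (A): {self.max_distance_violation:.3f}",
            f"  max dihedral violation (deg): {self.max_dihedral_violation:.3f}",
            "Deviations from idealized geometry",
            f"  bonds (A): {self.bond_rmsd_mean:.4f} +/- {self.bond_rmsd_sd:.4f}",
            f"  angles (deg): {self.angle_rmsd_mean:.3f} +/- {self.angle_rmsd_sd:.3f}",
            f"  impropers (deg): {self.improper_rmsd_mean:.3f}"
            f" +/- {self.improper_rmsd_sd:.3f}",
        ]
        if np.isfinite(self.rmsd_backbone_mean):
            lines += [
                "Average pairwise r.m.s.d. (A)",
                f"  backbone (N, CA, C): {self.rmsd_backbone_mean:.2f}"
                f" +/- {self.rmsd_backbone_sd:.2f}",
                f"  heavy: {self.rmsd_heavy_mean:.2f} +/- {self.rmsd_heavy_sd:.2f}",
            ]
        return "\n".join(lines)


def validate(ensemble, restraints, torsions,
             per_stage_energies: dict | None = None) -> ValidationReport:
    """Violation, geometry and precision statistics for a final ensemble.

    Ensemble members may be Structures or an Assembly's subunits. Distance
    violations use the r^-6 effective distance of ambiguous restraints; the
    reported mean is the per-conformer mean violation magnitude over
    restraints exceeding their upper bound, pooled as mean +/- sd across the
    ensemble.
    """
    if isinstance(ensemble, Assembly):
        ensemble = ensemble.subunits
    if not ensemble:
        raise ValueError("empty ensemble")
    members = list(ensemble)
    ref = members[0]
    if ref.topology is None or ref.topology.empty:
        from .structure import build_topology
        for m in members:
            build_topology(m)
    n_res = ref.n_residues
    summary = summarize_restraints(restraints, torsions, n_res)

    dist_term = DistanceRestraintTerm(restraints, ref, k=1.0)
    dih_term = TorsionRestraintTerm(torsions, ref, k=1.0)
    dist_means, dih_means = [], []
    max_dist = max_dih = 0.0
    geo = []
    for m in members:
        viol = dist_term.violations(m.coords)
        over = viol[viol > 0]
        dist_means.append(float(over.mean()) if len(over) else 0.0)
        max_dist = max(max_dist, float(np.abs(viol).max()) if len(viol) else 0.0)
        dviol = dih_term.violations_deg(m.coords)
        dover = dviol[dviol > 0]
        dih_means.append(float(dover.mean()) if len(dover) else 0.0)
        max_dih = max(max_dih, float(dviol.max()) if len(dviol) else 0.0)
        geo.append(geometry_deviations(m))
    geo = np.array(geo)

    kwargs = {}
    if len(members) >= 2:
        bb_mean, bb_sd, _ = pairwise_ensemble_rmsd(members, "backbone and name N,CA,C")
        hv_mean, hv_sd, _ = pairwise_ensemble_rmsd(members, "heavy")
        kwargs = dict(rmsd_backbone_mean=bb_mean, rmsd_backbone_sd=bb_sd,
                      rmsd_heavy_mean=hv_mean, rmsd_heavy_sd=hv_sd)
    return ValidationReport(
        restraint_summary=summary,
        distance_violation_mean=float(np.mean(dist_means)),
        distance_violation_sd=float(np.std(dist_means)),
        max_distance_violation=max_dist,
        dihedral_violation_mean=float(np.mean(dih_means)),
        dihedral_violation_sd=float(np.std(dih_means)),
        max_dihedral_violation=max_dih,
        bond_rmsd_mean=float(geo[:, 0].mean()), bond_rmsd_sd=float(geo[:, 0].std()),
        angle_rmsd_mean=float(geo[:, 1].mean()), angle_rmsd_sd=float(geo[:, 1].std()),
        improper_rmsd_mean=float(geo[:, 2].mean()),
        improper_rmsd_sd=float(geo[:, 2].std()),
        per_stage_energies=per_stage_energies or {},
        **kwargs)


def report_to_tsv(report: ValidationReport, path) -> None:
    """Flat key/value TSV of the validation statistics."""
    import pandas as pd
    rows = []
    for name, val in report.restraint_summary.__dict__.items():
        rows.append({"statistic": f"restraints.{name}", "value": val})
    for name in ("distance_violation_mean", "distance_violation_sd",
                 "max_distance_violation", "dihedral_violation_mean",
                 "dihedral_violation_sd", "max_dihedral_violation",
                 "bond_rmsd_mean", "bond_rmsd_sd", "angle_rmsd_mean",
                 "angle_rmsd_sd", "improper_rmsd_mean", "improper_rmsd_sd",
                 "rmsd_backbone_mean", "rmsd_backbone_sd",
                 "rmsd_heavy_mean", "rmsd_heavy_sd"):
        rows.append({"statistic": name, "value": getattr(report, name)})
    for stage, e in report.per_stage_energies.items():
        rows.append({"statistic": f"energy.{stage}", "value": e})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alternative-start validation

@dataclass
class AlternativeStartReport:
    final_rmsd_matrix: np.ndarray       # backbone RMSD between final structures
    start_rmsd_matrix: np.ndarray       # backbone RMSD between start models
    start_vs_final: np.ndarray          # per run
    finals: list = field(default_factory=list)

    @property
    def converged(self) -> bool:
        """Finals mutually closer than their (distinct) starts were."""
        n = len(self.start_vs_final)
        iu = np.triu_indices(n, 1)
        return bool(np.all(self.final_rmsd_matrix[iu] <
                           np.maximum(self.start_rmsd_matrix[iu], 1e-9)) or
                    np.allclose(self.start_rmsd_matrix[iu], 0.0))


def validate_alternative_starts(start_models, restraints, torsions,
                                envelope_map: DensityMap | None = None,
                                config: PipelineConfig | None = None) -> AlternativeStartReport:
    """Run stage 1 from each start model and compare the final structures."""
    config = config or PipelineConfig()
    if len(start_models) < 2:
        raise ValueError("need >= 2 start models")
    seq = start_models[0].sequence
    for k, m in enumerate(start_models[1:], start=1):
        if m.sequence != seq:
            raise ValueError(f"start model {k} has a different sequence")
    finals = []
    for k, start in enumerate(start_models):
        cfg = PipelineConfig(**{**config.__dict__, "seed": config.seed + 100 * k})
        best, _ = stage1_single_chain(start, restraints, torsions,
                                      envelope_map, cfg)
        finals.append(best)
    bb = "backbone and name N,CA,C"
    n = len(start_models)
    fmat = np.zeros((n, n))
    smat = np.zeros((n, n))
    svf = np.zeros(n)
    for i in range(n):
        svf[i] = superpose(start_models[i], finals[i], bb).rmsd
        for j in range(i + 1, n):
            fmat[i, j] = fmat[j, i] = superpose(finals[i], finals[j], bb).rmsd
            smat[i, j] = smat[j, i] = superpose(start_models[i], start_models[j], bb).rmsd
    return AlternativeStartReport(fmat, smat, svf, finals)


# ---------------------------------------------------------------------------
# end-to-end convenience

def run_pipeline(start_structure: Structure, restraints, torsions,
                 experimental_map: DensityMap, extra_restraints=(),
                 config: PipelineConfig | None = None) -> dict:
    """Stage 1 -> 2 -> 3 -> 4 plus validation; returns all intermediates."""
    config = config or PipelineConfig()
    chain, s1_results = stage1_single_chain(start_structure, restraints,
                                            torsions, None, config)
    placements = stage2_dock(chain, experimental_map, config.n_subunits, config)
    assembly, s3_best = stage3_joint_refine(chain, placements, restraints,
                                            torsions, experimental_map, config)
    final = stage4_neck_linker(assembly, extra_restraints, restraints, torsions,
                               experimental_map, config.free_range,
                               config.n_per_subunit, config)
    report = validate(final, list(restraints) + list(extra_restraints), torsions,
                      per_stage_energies={
                          "stage1": s1_results[0].energy,
                          "stage3": s3_best.energy})
    return {"chain": chain, "placements": placements, "assembly": assembly,
            "final": final, "report": report}
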