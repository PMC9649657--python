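"""Cross-peaks to distance restraints, restraint accounting, and two-state
peak-list comparison.

Assigned carbon-carbon cross-peaks become flat-bottom distance restraints
with fixed bounds: 1.5-6.5 A (target 4.0 +/- 2.5) for intra-residue pairs
and 2.0-7.2 A (4.6 +/- 2.6) for inter-residue pairs. Restraints with more
candidate assignments than the ambiguity limit (default 5) are dropped.
Sequence-separation classes: intra (i = j), sequential (|i-j| = 1), medium
(1 < |i-j| < 5), long (|i-j| >= 5). The medium-range convention is the
strict one, keeping sequential and medium disjoint (two conventions appear
in print; the strict form is adopted and noted here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTRA_BOUNDS = (1.5, 6.5, 4.0, 2.5)   # lower, upper, target, tolerance (A)
INTER_BOUNDS = (2.0, 7.2, 4.6, 2.6)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

CATEGORIES = ("intra", "sequential", "medium", "long", "ambiguous")


# ---------------------------------------------------------------------------
# types

Assignment = tuple  # (res_i, atom_i, res_j, atom_j)


@dataclass
class CrossPeak:
    experiment_id: str
    assignments: list          # list of (res_i, atom_i, res_j, atom_j)
    intensity: float | None = None
    shift_1: float | None = None
    shift_2: float | None = None

    def __post_init__(self):
        if not self.assignments:
            raise ValueError("a cross-peak needs at least one candidate assignment")
        self.assignments = [
            (int(i), str(ai), int(j), str(aj)) for (i, ai, j, aj) in self.assignments]
        for (i, _ai, j, _aj) in self.assignments:
            if i < 1 or j < 1:
                raise ValueError("residue indices must be >= 1")


@dataclass
class DistanceRestraint:
    assignments: list
    lower_bound: float
    upper_bound: float
    target: float
    tolerance: float
    category: str
    source_experiments: set = field(default_factory=set)

    def __post_init__(self):
        if not (0 < self.lower_bound < self.upper_bound):
            raise ValueError("bounds must satisfy 0 < lower < upper")
        if (len(self.assignments) > 1) != (self.category == "ambiguous"):
            raise ValueError("category 'ambiguous' iff multiple assignments")

    def key(self) -> frozenset:
        """Order-insensitive, atom-pair-symmetric identity of the restraint."""
        return frozenset(
            frozenset(((i, ai), (j, aj))) for (i, ai, j, aj) in self.assignments)


@dataclass
class TorsionRestraint:
    residue_index: int
    angle: str                 # "phi" or "psi"
    target: float              # degrees in (-180, 180]
    tolerance: float | None = None

    def __post_init__(self):
        if self.angle not in ("phi", "psi"):
            raise ValueError("angle must be 'phi' or 'psi'")
        if self.tolerance is not None and self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        # normalize into (-180, 180]
        t = (self.target + 180.0) % 360.0 - 180.0
        self.target = 180.0 if t == -180.0 else t


@dataclass
class StatePeakDelta:
    residue_index: int
    csp: float                 # ppm, >= 0
    intensity_ratio: float     # b / a, >= 0
    flag: str                  # shifted | attenuated | unchanged
    assignments: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# classification and bounds

def classify_contact(i: int, j: int) -> str:
    """Sequence-separation class of an unambiguous contact."""
    if i < 1 or j < 1:
        raise ValueError("residue indices must be positive")
    sep = abs(i - j)
    if sep == 0:
        return "intra"
    if sep == 1:
        return "sequential"
    if sep < 5:
        return "medium"
    return "long"


def assign_bounds(category_class: str):
    """Distance bounds (lower, upper, target, tolerance) per restraint class."""
    if category_class in ("intra", "intra-residue"):
        return INTRA_BOUNDS
    if category_class in ("inter", "inter-residue"):
        return INTER_BOUNDS
    raise ValueError(f"unknown restraint class {category_class!r}")


def _restraint_from_assignments(assignments, experiments) -> DistanceRestraint:
    # mixed ambiguous sets (some candidates intra, some inter) take the
    # looser inter-residue bounds: ambiguity must not over-restrain
    all_intra = all(i == j for (i, _ai, j, _aj) in assignments)
    lo, hi, target, tol = assign_bounds("intra" if all_intra else "inter")
    if len(assignments) > 1:
        category = "ambiguous"
    else:
        i, _ai, j, _aj = assignments[0]
        category = classify_contact(i, j)
    return DistanceRestraint(list(assignments), lo, hi, target, tol,
                             category, set(experiments))


def peaks_to_restraints(peaks, ambiguity_limit: int = 5):
    """Convert validated cross-peaks into non-redundant distance restraints.

    Peaks exceeding the ambiguity limit are dropped (and logged); peaks with
    identical assignment sets are merged, unioning their source experiments.
    """
    dropped = 0
    restraints = []
    for peak in peaks:
        if len(peak.assignments) > ambiguity_limit:
            dropped += 1
            logger.info("dropping peak with %d-fold ambiguity (limit %d)",
                        len(peak.assignments), ambiguity_limit)
            continue
        restraints.append(
            _restraint_from_assignments(peak.assignments, {peak.experiment_id}))
    if dropped:
        logger.info("%d peaks dropped for exceeding %d-fold ambiguity",
                    dropped, ambiguity_limit)
    return deduplicate(restraints)


def deduplicate(restraints) -> list:
    """Merge restraints with identical assignment sets (order-insensitive,
    atom-pair-symmetric), unioning source experiments. Idempotent."""
    merged: dict = {}
    order = []
    for r in restraints:
        k = r.key()
        if k in merged:
            merged[k].source_experiments |= r.source_experiments
        else:
            copy = DistanceRestraint(list(r.assignments), r.lower_bound,
                                     r.upper_bound, r.target, r.tolerance,
                                     r.category, set(r.source_experiments))
            merged[k] = copy
            order.append(k)
    return [merged[k] for k in order]


# ---------------------------------------------------------------------------
# accounting

@dataclass
class RestraintSummary:
    unambiguous: int = 0
    intra: int = 0
    inter: int = 0
    sequential: int = 0
    medium: int = 0
    long: int = 0
    long_sidechain_sidechain: int = 0
    ambiguous: int = 0
    total: int = 0
    restraints_per_residue: float = 0.0
    phi: int = 0
    psi: int = 0
    torsion_total: int = 0


def summarize_restraints(restraints, torsions, n_residues: int) -> RestraintSummary:
    """Count restraints per class; totals are sums of their parts."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    s = RestraintSummary()
    for r in restraints:
        if r.category == "ambiguous":
            s.ambiguous += 1
            continue
        s.unambiguous += 1
        if r.category == "intra":
            s.intra += 1
        else:
            s.inter += 1
            setattr(s, r.category, getattr(s, r.category) + 1)
            if r.category == "long":
                (i, ai, j, aj) = r.assignments[0]
                if ai not in BACKBONE_ATOMS and aj not in BACKBONE_ATOMS:
                    s.long_sidechain_sidechain += 1
    s.total = s.unambiguous + s.ambiguous
    s.restraints_per_residue = round(s.total / n_residues, 2)
    for t in torsions:
        if t.angle == "phi":
            s.phi += 1
        else:
            s.psi += 1
    s.torsion_total = s.phi + s.psi
    return s


def contact_matrix(restraints, n_residues: int,
                   include_ambiguous: bool = False) -> np.ndarray:
    """Symmetric matrix of inter-residue contact counts.

    Unambiguous restraints add 1 at (i, j) and (j, i); the diagonal holds
    intra-residue counts. With `include_ambiguous`, each candidate pair of
    an ambiguous restraint contributes 1/|assignments| (returns floats).
    """
    mat = np.zeros((n_residues, n_residues),
                   dtype=float if include_ambiguous else int)
    for r in restraints:
        if r.category == "ambiguous":
            if not include_ambiguous:
                continue
            w = 1.0 / len(r.assignments)
            for (i, _ai, j, _aj) in r.assignments:
                if i == j:
                    mat[i - 1, i - 1] += w
                else:
                    mat[i - 1, j - 1] += w
                    mat[j - 1, i - 1] += w
        else:
            (i, _ai, j, _aj) = r.assignments[0]
            if i == j:
                mat[i - 1, i - 1] += 1
            else:
                mat[i - 1, j - 1] += 1
                mat[j - 1, i - 1] += 1
    return mat


# ---------------------------------------------------------------------------
# two-state comparison

@dataclass
class ComparisonResult:
    deltas: list                       # per matched peak, StatePeakDelta
    residue_table: pd.DataFrame        # per-residue max CSP / min ratio / flag
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    def flagged_residues(self) -> set:
        t = self.residue_table
        return set(t.loc[t["flag"] != "unchanged", "residue"].astype(int))


def compare_states(peaks_a, peaks_b, csp_threshold: float = 0.1,
                   intensity_threshold: float = 0.5,
                   weights=(1.0, 1.0)) -> ComparisonResult:
    """Compare two states' peak lists (e.g. apo vs nucleotide-bound).

    Peaks are matched by (experiment, assignment set). Per matched peak the
    CSP is the weighted Euclidean shift displacement over the two spectral
    dimensions; intensity_ratio is b/a. Per-residue statistics attribute
    each shift dimension to the residue whose resonance it is (dimension 1
    to residue i, dimension 2 to residue j of the first assignment), so a
    perturbation localizes to the residues that actually moved.
    """
    def key(p):
        return (p.experiment_id, frozenset(
            frozenset(((i, ai), (j, aj))) for (i, ai, j, aj) in p.assignments))

    index_b = {key(p): p for p in peaks_b}
    matched_keys = set()
    deltas = []
    w1, w2 = weights
    per_res: dict = {}

    def upd(res, dshift, ratio):
        rec = per_res.setdefault(res, {"max_dshift": 0.0, "min_ratio": np.inf})
        rec["max_dshift"] = max(rec["max_dshift"], dshift)
        rec["min_ratio"] = min(rec["min_ratio"], ratio)

    for pa in peaks_a:
        k = key(pa)
        pb = index_b.get(k)
        if pb is None:
            continue
        matched_keys.add(k)
        d1 = abs((pb.shift_1 or 0.0) - (pa.shift_1 or 0.0))
        d2 = abs((pb.shift_2 or 0.0) - (pa.shift_2 or 0.0))
        csp = float(np.hypot(w1 * d1, w2 * d2))
        if pa.intensity in (None, 0) or pb.intensity is None:
            ratio = 1.0
        else:
            ratio = float(pb.intensity / pa.intensity)
        if csp > csp_threshold:
            flag = "shifted"
        elif ratio < intensity_threshold:
            flag = "attenuated"
        else:
            flag = "unchanged"
        (i, _ai, j, _aj) = pa.assignments[0]
        deltas.append(StatePeakDelta(i, csp, ratio, flag, list(pa.assignments)))
        upd(i, w1 * d1, ratio)
        upd(j, w2 * d2, ratio)

    unmatched_a = [p for p in peaks_a if key(p) not in matched_keys]
    unmatched_b = [p for p in peaks_b if key(p) not in matched_keys]
    if not deltas:
        warnings.warn("no matchable peaks between the two states")

    rows = []
    for res in sorted(per_res):
        rec = per_res[res]
        ratio = rec["min_ratio"] if np.isfinite(rec["min_ratio"]) else 1.0
        if rec["max_dshift"] > csp_threshold:
            flag = "shifted"
        elif ratio < intensity_threshold:
            flag = "attenuated"
        else:
            flag = "unchanged"
        rows.append({"residue": res, "max_csp": rec["max_dshift"],
                     "min_intensity_ratio": ratio, "flag": flag})
    table = pd.DataFrame(rows, columns=["residue", "max_csp",
                                        "min_intensity_ratio", "flag"])
    return ComparisonResult(deltas, table, unmatched_a, unmatched_b)


# ---------------------------------------------------------------------------
# tabular I/O

PEAK_COLUMNS = ["exp_id", "res_i", "atom_i", "res_j", "atom_j",
                "shift1_ppm", "shift2_ppm", "intensity", "alt_assignments"]


def _fmt_assignment(a: Assignment) -> str:
    i, ai, j, aj = a
    return f"{i}.{ai}-{j}.{aj}"


def _parse_assignment(token: str) -> Assignment:
    left, right = token.split("-")
    i, ai = left.split(".")
    j, aj = right.split(".")
    return (int(i), ai, int(j), aj)


def write_peaks_tsv(peaks, path) -> None:
    rows = []
    for p in peaks:
        (i, ai, j, aj) = p.assignments[0]
        alts = ";".join(_fmt_assignment(a) for a in p.assignments[1:])
        rows.append({"exp_id": p.experiment_id, "res_i": i, "atom_i": ai,
                     "res_j": j, "atom_j": aj,
                     "shift1_ppm": "" if p.shift_1 is None else f"{p.shift_1:.4f}",
                     "shift2_ppm": "" if p.shift_2 is None else f"{p.shift_2:.4f}",
                     "intensity": "" if p.intensity is None else f"{p.intensity:.4f}",
                     "alt_assignments": alts})
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"alt_assignments": str},
                     keep_default_na=False)
    peaks = []
    for _, row in df.iterrows():
        assignments = [(int(row["res_i"]), row["atom_i"],
                        int(row["res_j"]), row["atom_j"])]
        if row.get("alt_assignments", ""):
            assignments += [_parse_assignment(t)
                            for t in str(row["alt_assignments"]).split(";") if t]
        def _opt(v):
            return None if v in ("", None) else float(v)
        peaks.append(CrossPeak(str(row["exp_id"]), assignments,
                               intensity=_opt(row.get("intensity", "")),
                               shift_1=_opt(row.get("shift1_ppm", "")),
                               shift_2=_opt(row.get("shift2_ppm", ""))))
    return peaks


def write_torsions_tsv(torsions, path) -> None:
    rows = [{"residue": t.residue_index, "angle": t.angle,
             "target_deg": f"{t.target:.4f}",
             "tolerance_deg": "" if t.tolerance is None else f"{t.tolerance:.4f}"}
            for t in torsions]
    pd.DataFrame(rows, columns=["residue", "angle", "target_deg",
                                "tolerance_deg"]).to_csv(path, sep="\t", index=False)


def read_torsions_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        tol = row.get("tolerance_deg", "")
        out.append(TorsionRestraint(int(row["residue"]), str(row["angle"]),
                                    float(row["target_deg"]),
                                    None if tol in ("", None) else float(tol)))
    return out


def write_restraints_tsv(restraints, path) -> None:
    rows = []
    for r in restraints:
        rows.append({
            "category": r.category,
            "n_assignments": len(r.assignments),
            "assignments": ";".join(_fmt_assignment(a) for a in r.assignments),
            "lower_A": f"{r.lower_bound:.2f}", "upper_A": f"{r.upper_bound:.2f}",
            "target_A": f"{r.target:.2f}", "tolerance_A": f"{r.tolerance:.2f}",
            "experiments": ";".join(sorted(r.source_experiments)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_assign_table(restraints, path) -> None:
    """Generic 'assign (resid i and name X) (resid j and name Y) d dminus dplus'
    restraint text; OR lines carry the additional candidates of ambiguous
    restraints."""
    lines = []
    for r in restraints:
        dminus = r.target - r.lower_bound
        dplus = r.upper_bound - r.target
        (i, ai, j, aj) = r.assignments[0]
        line = (f"assign (resid {i} and name {ai}) (resid {j} and name {aj}) "
                f"{r.target:.2f} {dminus:.2f} {dplus:.2f}")
        lines.append(line)
        for (i2, ai2, j2, aj2) in r.assignments[1:]:
            lines.append(f"  or (resid {i2} and name {ai2}) "
                         f"(resid {j2} and name {aj2})")
    Path(path).write_text("\n".join(lines) + "\n")
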