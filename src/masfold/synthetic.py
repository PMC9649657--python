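"""Synthetic fixtures with known ground truth.

Generates everything the pipeline consumes: toy folds built from ideal
geometry, labeling-scheme-filtered carbon-carbon peak lists, torsion
restraints measured from the true coordinates, helical multi-copy lattices
with blurred density maps, and perturbed second-state peak lists.

The master guarantee: restraints derived from any generated fixture are
satisfied by the true coordinates (zero restraint energy before noise that
exceeds tolerances), and every generator is a deterministic function of its
parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import geometry
from .density import DensityMap, Placement, simulate_map
from .restraints import CrossPeak, TorsionRestraint
from .structure import (AA3_TO_1, Assembly, Structure, build_backbone,
                        N_SIDE_CARBONS)

# canonical backbone dihedrals per secondary-structure element (degrees)
ELEMENT_PHI_PSI = {
    "helix": (-60.0, -45.0),
    "strand": (-120.0, 120.0),
    "loop": (100.0, 125.0),    # turn angles that fold helices into a hairpin
}

# default sequence motif cycled to the requested length: a mix of side-chain
# sizes so all pseudo-carbon names (CB, CG, CD) are exercised
_SEQ_MOTIF = "ALEKVSTGIF"

_BASE_SHIFTS = {"C": 175.0, "CA": 56.0, "CB": 32.0, "CG": 27.0, "CD": 24.0}


@dataclass
class LabelingScheme:
    """NMR-visible carbons per residue type for one labeling pattern."""

    name: str
    visible: dict  # residue type (or "default") -> list of atom names

    def visible_atoms(self, res_name: str) -> set:
        atoms = self.visible.get(res_name, self.visible.get("default", []))
        carbons = {"CA", "C"} | set(
            n for n in ("CB", "CG", "CD")
            if ("CB", "CG", "CD").index(n) < N_SIDE_CARBONS.get(res_name, 0))
        return set(atoms) & carbons

    @staticmethod
    def load(name: str, path=None) -> "LabelingScheme":
        if path is None:
            text = resources.files("masfold.data").joinpath(
                "labeling_schemes.yaml").read_text()
        else:
            text = Path(path).read_text()
        table = yaml.safe_load(text)
        if name not in table:
            raise KeyError(f"unknown labeling scheme {name!r}; "
                           f"available: {sorted(table)}")
        return LabelingScheme(name, table[name])


@dataclass
class GroundTruth:
    structure: Structure | None = None
    assembly: Assembly | None = None
    placements: list = field(default_factory=list)
    contacts: list = field(default_factory=list)          # (i, ai, j, aj, d)
    perturbed_residues: list = field(default_factory=list)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "contacts": [[int(i), str(ai), int(j), str(aj), round(float(d), 4)]
                         for (i, ai, j, aj, d) in self.contacts],
            "perturbed_residues": list(map(int, self.perturbed_residues)),
            "placements": [
                {"rotation": np.round(p.rotation, 6).tolist(),
                 "translation": np.round(p.translation, 6).tolist()}
                for p in self.placements],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# toy folds

def _parse_topology_spec(spec: str, n_residues: int):
    tokens = [t.strip() for t in spec.split("-") if t.strip()]
    for t in tokens:
        if t not in ELEMENT_PHI_PSI:
            raise ValueError(f"unknown secondary-structure token {t!r}")
    n_loops = sum(1 for t in tokens if t == "loop")
    loop_len = 4
    n_ss = len(tokens) - n_loops
    remaining = n_residues - loop_len * n_loops
    if n_ss == 0:
        per_ss, extra = 0, 0
        loop_len = n_residues // max(n_loops, 1)
    else:
        per_ss, extra = divmod(remaining, n_ss)
    lengths = []
    for t in tokens:
        if t == "loop":
            lengths.append(loop_len)
        else:
            lengths.append(per_ss + (1 if extra > 0 else 0))
            extra -= 1
    # absorb any rounding drift into the final element
    lengths[-1] += n_residues - sum(lengths)
    return tokens, lengths


def make_toy_fold(n_residues: int, topology_spec: str = "helix-loop-helix",
                  seed: int = 0, sequence: str | None = None):
    """Ideal-geometry backbone + pseudo-sidechains with standard phi/psi per
    element. Deterministic per (parameters, seed)."""
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    tokens, lengths = _parse_topology_spec(topology_spec, n_residues)
    phi = np.empty(n_residues)
    psi = np.empty(n_residues)
    pos = 0
    for t, ln in zip(tokens, lengths):
        phi[pos:pos + ln], psi[pos:pos + ln] = ELEMENT_PHI_PSI[t]
        pos += ln
    if sequence is None:
        sequence = (_SEQ_MOTIF * (n_residues // len(_SEQ_MOTIF) + 1))[:n_residues]
    st = build_backbone(sequence, phi, psi)
    truth = GroundTruth(structure=st.copy(), seed=seed)
    return st, truth


# ---------------------------------------------------------------------------
# peak simulation

def _pseudo_shift(res_index: int, res_name: str, atom: str,
                  rng_shift: np.random.Generator | None = None) -> float:
    """Deterministic pseudo chemical shift (ppm) for a (residue, atom) site."""
    base = _BASE_SHIFTS.get(atom, 30.0)
    # residue-type and position-dependent offsets, deterministic (no RNG):
    type_off = (hash_ord(res_name) % 17) * 0.35 - 2.8
    pos_off = ((res_index * 37) % 23) * 0.12 - 1.3
    return base + type_off + pos_off


def hash_ord(name: str) -> int:
    return sum(ord(c) * (k + 1) for k, c in enumerate(name))


def simulate_peaks(structure: Structure, scheme: LabelingScheme,
                   cutoff: float = 7.2, ambiguity_rate: float = 0.0,
                   max_ambiguity: int = 5, noise: float = 0.0,
                   seed: int = 0, experiment_id: str | None = None):
    """One cross-peak per visible-carbon pair within `cutoff`.

    A seeded fraction `ambiguity_rate` of peaks receives 1 to
    (max_ambiguity - 1) decoy assignments; `noise` adds Gaussian ppm noise
    to the shifts. Every emitted true contact is within the cutoff, so the
    derived restraints are satisfied by the true coordinates.
    """
    rng = np.random.default_rng(seed)
    exp_id = experiment_id or f"CORD_{scheme.name}"
    sites = []   # (res_index, res_name, atom_name, coord)
    for c, r, rn, span in structure.residue_spans():
        vis = scheme.visible_atoms(rn)
        if not vis and scheme.visible:
            continue
        for i in span:
            if structure.atom_names[i] in vis:
                sites.append((r, rn, structure.atom_names[i], structure.coords[i]))
    if not sites:
        raise ValueError(f"labeling scheme {scheme.name!r} leaves no visible atoms")
    peaks, truth_contacts = [], []
    if cutoff <= 0:
        return peaks, GroundTruth(structure=structure.copy(), seed=seed)
    coords = np.array([s[3] for s in sites])
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    n = len(sites)
    all_pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    close = [(a, b) for (a, b) in all_pairs if dmat[a, b] <= cutoff]
    for (a, b) in close:
        ri, rni, ai = sites[a][0], sites[a][1], sites[a][2]
        rj, rnj, aj = sites[b][0], sites[b][1], sites[b][2]
        d = float(dmat[a, b])
        s1 = _pseudo_shift(ri, rni, ai) + (rng.normal(0, noise) if noise else 0.0)
        s2 = _pseudo_shift(rj, rnj, aj) + (rng.normal(0, noise) if noise else 0.0)
        intensity = float((4.0 / max(d, 1.5)) ** 6)
        assignments = [(ri, ai, rj, aj)]
        if ambiguity_rate > 0 and rng.random() < ambiguity_rate:
            n_decoys = int(rng.integers(1, max_ambiguity))
            decoys, dists = [], [d]
            for _ in range(n_decoys):
                ca, cb = rng.integers(0, n, size=2)
                if ca == cb or dmat[ca, cb] < 4.0:
                    continue
                dec = (sites[ca][0], sites[ca][2], sites[cb][0], sites[cb][2])
                if dec not in assignments and dec not in decoys:
                    decoys.append(dec)
                    dists.append(float(dmat[ca, cb]))
            # keep decoys only if the r^-6 effective distance of the full
            # candidate set stays inside the looser inter-residue bounds,
            # so the true coordinates never violate the emitted restraint
            d_eff = float(np.sum(np.asarray(dists) ** -6.0) ** (-1.0 / 6.0))
            if decoys and d_eff >= 2.1:
                assignments.extend(decoys)
        peaks.append(CrossPeak(exp_id, assignments, intensity=intensity,
                               shift_1=s1, shift_2=s2))
        truth_contacts.append((ri, ai, rj, aj, d))
    truth = GroundTruth(structure=structure.copy(), contacts=truth_contacts,
                        seed=seed)
    return peaks, truth


def simulate_torsions(structure: Structure, tolerance: float = 20.0,
                      noise: float = 0.0, seed: int = 0):
    """phi/psi restraints measured from the true coordinates.

    Targets get Gaussian noise of width `noise` degrees; the true structure
    violates nothing as long as each draw stays within the tolerance.
    """
    if structure.n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    out = []
    resis = sorted({r for r in structure.res_indices})
    for r in resis:
        for angle in ("phi", "psi"):
            from .energy import _phi_psi_quad
            quad = _phi_psi_quad(structure, r, angle, None)
            if quad is None:
                continue
            val = np.rad2deg(geometry.dihedral_values(
                structure.coords, np.array([quad])))[0]
            target = val + (rng.normal(0.0, noise) if noise else 0.0)
            out.append(TorsionRestraint(int(r), angle, float(target), tolerance))
    return out


# ---------------------------------------------------------------------------
# lattice + map

def make_lattice(structure: Structure, n_copies: int = 4, spacing: float = 28.0,
                 axial_rise: float = 12.0, twist: float = 90.0,
                 resolution: float = 8.0, voxel: float = 2.0, seed: int = 0):
    """Place copies on a helical lattice (rise + twist about z), simulate the
    blurred map, and record the true placements.

    Copy k sits at radius `spacing` from the z axis, rotated by k*twist deg
    and raised by k*axial_rise A. Raises on steric clash between copies.
    """
    centered = structure.coords - structure.coords.mean(axis=0)
    base = centered + np.array([spacing, 0.0, 0.0])
    placements, subunits = [], []
    center0 = structure.coords.mean(axis=0)
    for k in range(n_copies):
        ang = np.deg2rad(twist * k)
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                       [np.sin(ang), np.cos(ang), 0.0],
                       [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, axial_rise * k])
        coords_k = base @ Rz.T + shift
        # absolute transform mapping the input structure onto this copy
        t = Rz @ (np.array([spacing, 0.0, 0.0]) - center0) + shift
        placements.append(Placement(Rz, t))
        sub = structure.copy()
        sub.coords = coords_k
        subunits.append(sub)
    for a in range(n_copies):
        for b in range(a + 1, n_copies):
            d = np.linalg.norm(subunits[a].coords[:, None, :]
                               - subunits[b].coords[None, :, :], axis=2)
            if d.min() < 2.0:
                raise ValueError(
                    f"copies {a} and {b} clash (min distance {d.min():.2f} A); "
                    "increase spacing or axial_rise")
    assembly = Assembly(subunits, [chr(ord("A") + i) for i in range(n_copies)])
    dmap = simulate_map([s.coords for s in subunits], resolution, voxel)
    truth = GroundTruth(structure=structure.copy(), assembly=assembly,
                        placements=placements, seed=seed)
    return assembly, dmap, truth


# ---------------------------------------------------------------------------
# two-state perturbation

def perturb_state(structure: Structure, peaks, perturbed_residues,
                  shift_delta: float = 0.3, intensity_factor: float = 0.5,
                  seed: int = 0):
    """Second-state peak list: shift dimensions belonging to perturbed
    residues are displaced by +/- shift_delta (seeded sign) and intensities
    of peaks touching perturbed residues are scaled by intensity_factor."""
    rng = np.random.default_rng(seed)
    perturbed = set(int(r) for r in perturbed_residues)
    out = []
    for p in peaks:
        (i, ai, j, aj) = p.assignments[0]
        s1, s2 = p.shift_1, p.shift_2
        inten = p.intensity
        touched = False
        if i in perturbed and s1 is not None:
            s1 = s1 + shift_delta * (1 if rng.random() < 0.5 else -1)
            touched = True
        if j in perturbed and s2 is not None:
            s2 = s2 + shift_delta * (1 if rng.random() < 0.5 else -1)
            touched = True
        if touched and inten is not None:
            inten = inten * intensity_factor
        out.append(CrossPeak(p.experiment_id, list(p.assignments),
                             intensity=inten, shift_1=s1, shift_2=s2))
    truth = GroundTruth(structure=structure.copy(),
                        perturbed_residues=sorted(perturbed), seed=seed)
    return out, truth


# ---------------------------------------------------------------------------
# the standard fixture

FIXTURE_A = dict(n_residues=30, topology_spec="helix-loop-helix",
                 scheme="glucose_16", cutoff=7.2, ambiguity_rate=0.15,
                 n_copies=4, spacing=28.0, axial_rise=12.0, twist=90.0,
                 resolution=8.0, voxel=2.0, seed=7)


def make_fixture_a(seed: int | None = None):
    """The standard test fixture: a 30-residue helix-loop-helix chain, a
    glucose_16-filtered peak list, torsions, a 4-copy helical lattice and
    its 8 A map. Returns a dict with all pieces plus ground truth."""
    p = dict(FIXTURE_A)
    if seed is not None:
        p["seed"] = seed
    st, truth_fold = make_toy_fold(p["n_residues"], p["topology_spec"], p["seed"])
    scheme = LabelingScheme.load(p["scheme"])
    peaks, truth_peaks = simulate_peaks(st, scheme, cutoff=p["cutoff"],
                                        ambiguity_rate=p["ambiguity_rate"],
                                        seed=p["seed"])
    torsions = simulate_torsions(st, tolerance=20.0, noise=0.0, seed=p["seed"])
    assembly, dmap, truth_lattice = make_lattice(
        st, p["n_copies"], p["spacing"], p["axial_rise"], p["twist"],
        p["resolution"], p["voxel"], p["seed"])
    return {"structure": st, "peaks": peaks, "torsions": torsions,
            "assembly": assembly, "map": dmap,
            "placements": truth_lattice.placements,
            "contacts": truth_peaks.contacts, "params": p}
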