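"""Structures, assemblies, coordinate I/O, superposition and ensemble statistics.

The internal model is heavy-atom only: backbone N, CA, C, O plus up to three
pseudo side-chain carbons (CB, CG, CD) per residue. Residue numbering is
1-based and matches author numbering; chains of an assembly are named by
segment id. Coordinate files are read and written through gemmi (PDB and
mmCIF).
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import yaml

from . import geometry

# ---------------------------------------------------------------------------
# residue tables

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# number of pseudo side-chain carbons (CB, CG, CD) in the reduced model
N_SIDE_CARBONS = {
    "GLY": 0,
    "ALA": 1,
    "SER": 2, "CYS": 2, "THR": 2, "VAL": 2, "ASP": 2, "ASN": 2, "PRO": 2,
    "LEU": 3, "ILE": 3, "MET": 3, "LYS": 3, "ARG": 3, "GLU": 3, "GLN": 3,
    "PHE": 3, "TYR": 3, "TRP": 3, "HIS": 3,
}
SIDE_NAMES = ("CB", "CG", "CD")
BACKBONE_NAMES = ("N", "CA", "C", "O")

ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "S": 32.06, "P": 30.974}


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB-style atom name (protein heavy atoms)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first in ("C", "N", "O", "S", "H", "P"):
        return first
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def load_ideal_geometry(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("masfold.data").joinpath("ideal_geometry.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# topology

@dataclass
class Topology:
    """Covalent topology with ideal values (lengths in A, angles in degrees)."""

    bonds: np.ndarray            # (m, 2) atom indices
    bond_ideal: np.ndarray
    angles: np.ndarray           # (m, 3)
    angle_ideal: np.ndarray      # degrees
    impropers: np.ndarray        # (m, 4)
    improper_ideal: np.ndarray   # degrees
    force_constants: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.bonds) == 0 and len(self.angles) == 0

    def shifted(self, offset: int) -> "Topology":
        return Topology(
            self.bonds + offset, self.bond_ideal.copy(),
            self.angles + offset, self.angle_ideal.copy(),
            self.impropers + offset, self.improper_ideal.copy(),
            dict(self.force_constants),
        )

    @staticmethod
    def concatenate(tops: list["Topology"]) -> "Topology":
        return Topology(
            np.concatenate([t.bonds for t in tops]),
            np.concatenate([t.bond_ideal for t in tops]),
            np.concatenate([t.angles for t in tops]),
            np.concatenate([t.angle_ideal for t in tops]),
            np.concatenate([t.impropers for t in tops]),
            np.concatenate([t.improper_ideal for t in tops]),
            dict(tops[0].force_constants) if tops else {},
        )


# ---------------------------------------------------------------------------
# Structure

class Structure:
    """Ordered atoms with coordinates, residue/chain bookkeeping and topology."""

    def __init__(self, chain_ids, res_indices, res_names, atom_names,
                 elements, coords, topology: Topology | None = None):
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.res_indices = np.asarray(res_indices, dtype=int)
        self.res_names = np.asarray(res_names, dtype=object)
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for arr in (self.chain_ids, self.res_indices, self.res_names,
                    self.atom_names, self.elements):
            if len(arr) != n:
                raise ValueError("atom attribute arrays must have equal length")
        self.topology = topology
        self._index_cache: dict | None = None

    # -- basic properties ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len({(c, r) for c, r in zip(self.chain_ids, self.res_indices)})

    @property
    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASS[e] for e in self.elements])

    @property
    def sequence(self) -> str:
        seen = []
        prev = None
        for c, r, rn in zip(self.chain_ids, self.res_indices, self.res_names):
            if (c, r) != prev:
                seen.append(AA3_TO_1.get(rn, "X"))
                prev = (c, r)
        return "".join(seen)

    def copy(self) -> "Structure":
        return Structure(self.chain_ids.copy(), self.res_indices.copy(),
                         self.res_names.copy(), self.atom_names.copy(),
                         self.elements.copy(), self.coords.copy(),
                         _copy.deepcopy(self.topology))

    # -- lookups ------------------------------------------------------------
    def atom_index(self, resi: int, name: str, chain: str | None = None) -> int:
        if self._index_cache is None:
            self._index_cache = {}
            for i, (c, r, nm) in enumerate(zip(self.chain_ids, self.res_indices,
                                               self.atom_names)):
                self._index_cache.setdefault((r, nm), []).append(i)
                self._index_cache[(c, r, nm)] = i
        if chain is not None:
            key = (chain, resi, name)
            if key not in self._index_cache:
                raise KeyError(f"atom {chain}/{resi}/{name} not found")
            return self._index_cache[key]
        hits = self._index_cache.get((resi, name), [])
        if not hits:
            raise KeyError(f"atom {resi}/{name} not found")
        if len(hits) > 1:
            raise KeyError(f"atom {resi}/{name} ambiguous across chains")
        return hits[0]

    def select(self, expr) -> np.ndarray:
        """Selection mini-language: tokens joined by ' and '.

        Supported tokens: 'backbone', 'heavy', 'all', 'name CA[,CB,...]',
        'resi 321-349[,5,...]', 'chain A[,B]'. An ndarray/list of indices
        passes through unchanged; None selects everything.
        """
        if expr is None:
            return np.arange(self.n_atoms)
        if isinstance(expr, (np.ndarray, list, tuple)) and not isinstance(expr, str):
            return np.asarray(expr, dtype=int)
        mask = np.ones(self.n_atoms, dtype=bool)
        for token in str(expr).split(" and "):
            token = token.strip()
            if not token or token == "all":
                continue
            if token == "backbone":
                mask &= np.isin(self.atom_names, BACKBONE_NAMES)
            elif token == "heavy":
                mask &= self.elements != "H"
            elif token.startswith("name "):
                names = [t.strip() for t in token[5:].split(",")]
                mask &= np.isin(self.atom_names, names)
            elif token.startswith("chain "):
                chains = [t.strip() for t in token[6:].split(",")]
                mask &= np.isin(self.chain_ids, chains)
            elif token.startswith("resi "):
                keep = np.zeros(self.n_atoms, dtype=bool)
                for part in token[5:].split(","):
                    part = part.strip()
                    if "-" in part[1:]:
                        lo, hi = part.rsplit("-", 1) if not part.startswith("-") else (part, part)
                        lo, hi = int(lo), int(hi)
                    else:
                        lo = hi = int(part)
                    keep |= (self.res_indices >= lo) & (self.res_indices <= hi)
                mask &= keep
            else:
                raise ValueError(f"unknown selection token {token!r}")
        return np.flatnonzero(mask)

    def residue_spans(self):
        """Yield (chain, resi, resname, index_array) per residue in order."""
        start = 0
        n = self.n_atoms
        while start < n:
            c, r = self.chain_ids[start], self.res_indices[start]
            end = start
            while end < n and self.chain_ids[end] == c and self.res_indices[end] == r:
                end += 1
            yield c, r, self.res_names[start], np.arange(start, end)
            start = end


# ---------------------------------------------------------------------------
# assembly

class Assembly:
    """Multiple copies of one chain sharing a topology template."""

    def __init__(self, subunits: list[Structure], segment_ids: list[str]):
        if len(subunits) != len(segment_ids):
            raise ValueError("one segment id per subunit required")
        if len(set(segment_ids)) != len(segment_ids):
            raise ValueError("segment ids must be unique")
        ref_names = subunits[0].atom_names
        for s in subunits[1:]:
            if s.n_atoms != subunits[0].n_atoms or not np.all(s.atom_names == ref_names):
                raise ValueError("all subunits must share identical atom ordering")
        self.subunits = subunits
        self.segment_ids = list(segment_ids)

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def copy(self) -> "Assembly":
        return Assembly([s.copy() for s in self.subunits], list(self.segment_ids))

    def to_structure(self) -> Structure:
        """Concatenate subunits into one Structure; chains named by segment id."""
        n_per = self.subunits[0].n_atoms
        tops = []
        chains, resi, resn, names, elems, coords = [], [], [], [], [], []
        for k, (sub, seg) in enumerate(zip(self.subunits, self.segment_ids)):
            chains.append(np.full(n_per, seg, dtype=object))
            resi.append(sub.res_indices)
            resn.append(sub.res_names)
            names.append(sub.atom_names)
            elems.append(sub.elements)
            coords.append(sub.coords)
            if sub.topology is not None:
                tops.append(sub.topology.shifted(k * n_per))
        top = Topology.concatenate(tops) if tops else None
        return Structure(np.concatenate(chains), np.concatenate(resi),
                         np.concatenate(resn), np.concatenate(names),
                         np.concatenate(elems), np.vstack(coords), top)

    def set_coords(self, coords: np.ndarray) -> None:
        n_per = self.subunits[0].n_atoms
        coords = coords.reshape(self.n_subunits, n_per, 3)
        for sub, block in zip(self.subunits, coords):
            sub.coords = block.copy()


def replicate_subunits(structure: Structure, n: int,
                       segment_ids: list[str] | None = None) -> Assembly:
    """n deep copies of a chain with independent coordinates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if segment_ids is None:
        segment_ids = [chr(ord("A") + i) for i in range(n)]
    return Assembly([structure.copy() for _ in range(n)], segment_ids)


# ---------------------------------------------------------------------------
# topology construction

def build_topology(structure: Structure, params: dict | None = None) -> Topology:
    """Build bonds/angles/impropers with ideal values from the residue model.

    Unknown atom names are skipped with a warning; the table covers the
    reduced heavy-atom representation (N, CA, C, O, CB, CG, CD).
    """
    par = params or load_ideal_geometry()
    b_ideal = par["bonds"]
    a_ideal = par["angles"]
    i_ideal = par["impropers"]

    bonds, blen, angles, aval, imps, ival = [], [], [], [], [], []

    spans = list(structure.residue_spans())
    idx_of = {}
    for c, r, rn, span in spans:
        for i in span:
            idx_of[(c, r, structure.atom_names[i])] = i

    def get(c, r, name):
        return idx_of.get((c, r, name))

    def add_bond(i, j, key):
        bonds.append((i, j)); blen.append(b_ideal[key])

    def add_angle(i, j, k, key):
        angles.append((i, j, k)); aval.append(a_ideal[key])

    known = set(BACKBONE_NAMES) | set(SIDE_NAMES)
    for c, r, rn, span in spans:
        for i in span:
            if structure.atom_names[i] not in known:
                warnings.warn(f"atom {structure.atom_names[i]} in residue {r} "
                              "not covered by the reduced topology; skipped")
        N, CA, C, O = (get(c, r, nm) for nm in BACKBONE_NAMES)
        CB, CG, CD = (get(c, r, nm) for nm in SIDE_NAMES)
        if N is not None and CA is not None:
            add_bond(N, CA, "N-CA")
        if CA is not None and C is not None:
            add_bond(CA, C, "CA-C")
        if C is not None and O is not None:
            add_bond(C, O, "C-O")
            if CA is not None:
                add_angle(CA, C, O, "CA-C-O")
        if N is not None and CA is not None and C is not None:
            add_angle(N, CA, C, "N-CA-C")
        if CB is not None and CA is not None:
            add_bond(CA, CB, "CA-CB")
            if N is not None:
                add_angle(N, CA, CB, "N-CA-CB")
            if C is not None and N is not None:
                imps.append((C, N, CA, CB)); ival.append(i_ideal["CB_chirality"])
        if CG is not None and CB is not None:
            add_bond(CB, CG, "CB-CG")
            if CA is not None:
                add_angle(CA, CB, CG, "CA-CB-CG")
        if CD is not None and CG is not None:
            add_bond(CG, CD, "CG-CD")
            if CB is not None:
                add_angle(CB, CG, CD, "CB-CG-CD")
        # peptide link to the following residue (same chain, consecutive index)
        Nn = get(c, r + 1, "N")
        CAn = get(c, r + 1, "CA")
        if C is not None and Nn is not None:
            add_bond(C, Nn, "C-N")
            if CA is not None:
                add_angle(CA, C, Nn, "CA-C-N")
            if O is not None:
                add_angle(O, C, Nn, "O-C-N")
                if CA is not None:
                    imps.append((Nn, CA, C, O)); ival.append(i_ideal["peptide_O"])
            if CAn is not None:
                add_angle(C, Nn, CAn, "C-N-CA")

    top = Topology(
        np.array(bonds, dtype=int).reshape(-1, 2), np.array(blen, dtype=float),
        np.array(angles, dtype=int).reshape(-1, 3), np.array(aval, dtype=float),
        np.array(imps, dtype=int).reshape(-1, 4), np.array(ival, dtype=float),
        dict(par.get("force_constants", {})),
    )
    structure.topology = top
    return top


# ---------------------------------------------------------------------------
# coordinate file I/O (gemmi-backed)

def _to_gemmi(ensemble: list[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "masfold"
    for im, member in enumerate(ensemble, start=1):
        model = gemmi.Model(im)
        for chain_name in dict.fromkeys(member.chain_ids):
            chain = gemmi.Chain(str(chain_name))
            sel = member.chain_ids == chain_name
            prev = None
            res = None
            for i in np.flatnonzero(sel):
                key = member.res_indices[i]
                if key != prev:
                    res = gemmi.Residue()
                    res.name = str(member.res_names[i])
                    res.seqid = gemmi.SeqId(int(key), " ")
                    chain.add_residue(res)
                    prev = key
                at = gemmi.Atom()
                at.name = str(member.atom_names[i])
                at.element = gemmi.Element(str(member.elements[i]))
                x, y, z = member.coords[i]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                chain[-1].add_atom(at)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def _from_gemmi_model(model: gemmi.Model) -> Structure:
    chains, resi, resn, names, elems, coords = [], [], [], [], [], []
    for chain in model:
        for res in chain:
            if res.name not in AA3_TO_1:
                warnings.warn(f"unknown residue {res.name}; atoms kept")
            for at in res:
                chains.append(chain.name)
                resi.append(res.seqid.num)
                resn.append(res.name)
                names.append(at.name)
                el = at.element.name if at.element and at.element.name != "X" else None
                elems.append(el if el else infer_element(at.name))
                coords.append([at.pos.x, at.pos.y, at.pos.z])
    return Structure(chains, resi, resn, names, elems, np.array(coords))


def read_ensemble(path: str | Path, fmt: str | None = None) -> list[Structure]:
    """Read all MODELs of a PDB/mmCIF file as a list of Structures."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    return [_from_gemmi_model(m) for m in st]


def read_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read the first model of a coordinate file."""
    return read_ensemble(path, fmt)[0]


def write_structure(structure, path: str | Path, fmt: str | None = None) -> None:
    """Write a Structure (or list of Structures as a multi-MODEL file)."""
    path = Path(path)
    fmt = fmt or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    ensemble = structure if isinstance(structure, (list, tuple)) else [structure]
    st = _to_gemmi(list(ensemble))
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


# ---------------------------------------------------------------------------
# superposition and ensemble statistics

@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(reference: Structure, mobile: Structure,
              selection=None) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of mobile onto reference."""
    sel_ref = reference.select(selection)
    sel_mob = mobile.select(selection)
    if len(sel_ref) != len(sel_mob):
        raise ValueError(
            f"selection maps to {len(sel_ref)} reference vs {len(sel_mob)} mobile atoms")
    R, t, rmsd = geometry.kabsch(reference.coords[sel_ref], mobile.coords[sel_mob])
    return SuperpositionResult(R, t, rmsd)


def pairwise_ensemble_rmsd(ensemble: list[Structure], selection="backbone"):
    """Mean/sd RMSD over all unordered pairs, each superposed on `selection`."""
    if len(ensemble) < 2:
        raise ValueError("need >= 2 ensemble members")
    ref_names = ensemble[0].atom_names
    for k, s in enumerate(ensemble[1:], start=1):
        if s.n_atoms != ensemble[0].n_atoms:
            raise ValueError(f"member {k} has {s.n_atoms} atoms vs {ensemble[0].n_atoms}")
        mismatch = np.flatnonzero(s.atom_names != ref_names)
        if len(mismatch):
            i = mismatch[0]
            raise ValueError(
                f"member {k} atom {i}: {s.atom_names[i]} != {ref_names[i]}")
    n = len(ensemble)
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(ensemble[i], ensemble[j], selection).rmsd
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    vals = np.array(vals)
    return float(vals.mean()), float(vals.std(ddof=0)), mat


def geometry_deviations(structure: Structure, coords: np.ndarray | None = None):
    """RMS deviation of bonds (A), angles (deg) and impropers (deg) from ideal."""
    top = structure.topology
    if top is None or top.empty:
        raise ValueError("structure has no populated topology")
    x = structure.coords if coords is None else coords
    bond_rmsd = angle_rmsd = improper_rmsd = 0.0
    if len(top.bonds):
        d = geometry.bond_lengths(x, top.bonds) - top.bond_ideal
        bond_rmsd = float(np.sqrt(np.mean(d ** 2)))
    if len(top.angles):
        d = np.rad2deg(geometry.angle_values(x, top.angles)) - top.angle_ideal
        angle_rmsd = float(np.sqrt(np.mean(d ** 2)))
    if len(top.impropers):
        d = np.rad2deg(geometry.wrap_angle(
            geometry.dihedral_values(x, top.impropers) - np.deg2rad(top.improper_ideal)))
        improper_rmsd = float(np.sqrt(np.mean(d ** 2)))
    return bond_rmsd, angle_rmsd, improper_rmsd


# ---------------------------------------------------------------------------
# chain building / extension

_EXTENDED_PHI = -135.0
_EXTENDED_PSI = 135.0


def _sidechain_positions(par, n_pos, ca_pos, c_pos, n_side):
    """Place pseudo side-chain carbons off CA with ideal covalent geometry."""
    out = []
    if n_side >= 1:
        cb = geometry.place_atom(c_pos, n_pos, ca_pos, par["bonds"]["CA-CB"],
                                 np.deg2rad(par["angles"]["N-CA-CB"]),
                                 np.deg2rad(par["impropers"]["CB_chirality"]))
        out.append(("CB", cb))
    if n_side >= 2:
        cg = geometry.place_atom(n_pos, ca_pos, out[0][1], par["bonds"]["CB-CG"],
                                 np.deg2rad(par["angles"]["CA-CB-CG"]),
                                 np.deg2rad(-60.0))
        out.append(("CG", cg))
    if n_side >= 3:
        cd = geometry.place_atom(ca_pos, out[0][1], out[1][1], par["bonds"]["CG-CD"],
                                 np.deg2rad(par["angles"]["CB-CG-CD"]),
                                 np.deg2rad(180.0))
        out.append(("CD", cd))
    return out


def build_backbone(sequence: str, phi: np.ndarray, psi: np.ndarray,
                   params: dict | None = None, chain_id: str = "A",
                   start_resi: int = 1) -> Structure:
    """Build an ideal-geometry chain from a sequence and phi/psi arrays.

    phi[0] and psi[-1] are not used to place backbone atoms (chain ends);
    psi[-1] still orients the final carbonyl oxygen.
    """
    par = params or load_ideal_geometry()
    nres = len(sequence)
    phi = np.deg2rad(np.asarray(phi, float))
    psi = np.deg2rad(np.asarray(psi, float))
    if len(phi) != nres or len(psi) != nres:
        raise ValueError("phi/psi arrays must match sequence length")
    b, a = par["bonds"], {k: np.deg2rad(v) for k, v in par["angles"].items()}
    omega = np.pi

    backbone = np.zeros((nres, 3, 3))  # N, CA, C
    backbone[0, 0] = (0.0, 0.0, 0.0)
    backbone[0, 1] = (b["N-CA"], 0.0, 0.0)
    backbone[0, 2] = geometry.place_atom(
        np.array([0.0, 1.0, 0.0]), backbone[0, 0], backbone[0, 1],
        b["CA-C"], a["N-CA-C"], phi[0] if nres > 1 else 0.0)
    for i in range(1, nres):
        Np, CAp, Cp = backbone[i - 1]
        N = geometry.place_atom(Np, CAp, Cp, b["C-N"], a["CA-C-N"], psi[i - 1])
        CA = geometry.place_atom(CAp, Cp, N, b["N-CA"], a["C-N-CA"], omega)
        C = geometry.place_atom(Cp, N, CA, b["CA-C"], a["N-CA-C"], phi[i])
        backbone[i] = (N, CA, C)

    chains, resis, resns, names, elems, coords = [], [], [], [], [], []
    for i, letter in enumerate(sequence):
        resn = AA1_TO_3[letter.upper()]
        N, CA, C = backbone[i]
        psi_i = psi[i] if i < nres - 1 else np.pi
        O = geometry.place_atom(N, CA, C, b["C-O"], a["CA-C-O"], psi_i + np.pi)
        atoms = [("N", N, "N"), ("CA", CA, "C"), ("C", C, "C"), ("O", O, "O")]
        for nm, pos in _sidechain_positions(par, N, CA, C, N_SIDE_CARBONS[resn]):
            atoms.append((nm, pos, "C"))
        for nm, pos, el in atoms:
            chains.append(chain_id)
            resis.append(start_resi + i)
            resns.append(resn)
            names.append(nm)
            elems.append(el)
            coords.append(pos)
    st = Structure(chains, resis, resns, names, elems, np.array(coords))
    build_topology(st, par)
    return st


def _grow_forward(par, anchor, letters, start_resi, chain_id,
                  first_psi: float | None = None):
    """Grow residues after an anchor (N, CA, C positions) in extended form.

    `first_psi` pins the torsion used to place the first new N: the anchor
    residue's psi is already fixed by its carbonyl O, and the new N must sit
    anti to it.
    """
    b, a = par["bonds"], {k: np.deg2rad(v) for k, v in par["angles"].items()}
    phi, psi, omega = np.deg2rad(_EXTENDED_PHI), np.deg2rad(_EXTENDED_PSI), np.pi
    Np, CAp, Cp = anchor
    out = []
    for k, letter in enumerate(letters):
        resn = AA1_TO_3[letter.upper()]
        psi_here = first_psi if (k == 0 and first_psi is not None) else psi
        N = geometry.place_atom(Np, CAp, Cp, b["C-N"], a["CA-C-N"], psi_here)
        CA = geometry.place_atom(CAp, Cp, N, b["N-CA"], a["C-N-CA"], omega)
        C = geometry.place_atom(Cp, N, CA, b["CA-C"], a["N-CA-C"], phi)
        O = geometry.place_atom(N, CA, C, b["C-O"], a["CA-C-O"], psi + np.pi)
        atoms = [("N", N, "N"), ("CA", CA, "C"), ("C", C, "C"), ("O", O, "O")]
        for nm, pos in _sidechain_positions(par, N, CA, C, N_SIDE_CARBONS[resn]):
            atoms.append((nm, pos, "C"))
        out.append((start_resi + k, resn, atoms))
        Np, CAp, Cp = N, CA, C
    return out


def _grow_backward(par, anchor, letters, end_resi, chain_id):
    """Grow residues before an anchor (its N, CA, C), highest index first."""
    b, a = par["bonds"], {k: np.deg2rad(v) for k, v in par["angles"].items()}
    phi, psi, omega = np.deg2rad(_EXTENDED_PHI), np.deg2rad(_EXTENDED_PSI), np.pi
    Nn, CAn, Cn = anchor
    out = []
    for k, letter in enumerate(reversed(letters)):
        resn = AA1_TO_3[letter.upper()]
        # reversed dihedrals equal the forward ones (torsion reversal symmetry)
        C = geometry.place_atom(Cn, CAn, Nn, b["C-N"], a["C-N-CA"], phi)
        CA = geometry.place_atom(CAn, Nn, C, b["CA-C"], a["CA-C-N"], omega)
        N = geometry.place_atom(Nn, C, CA, b["N-CA"], a["N-CA-C"], psi)
        O = geometry.place_atom(N, CA, C, b["C-O"], a["CA-C-O"], psi + np.pi)
        atoms = [("N", N, "N"), ("CA", CA, "C"), ("C", C, "C"), ("O", O, "O")]
        for nm, pos in _sidechain_positions(par, N, CA, C, N_SIDE_CARBONS[resn]):
            atoms.append((nm, pos, "C"))
        out.append((end_resi - k, resn, atoms))
        Nn, CAn, Cn = N, CA, C
    return list(reversed(out))


def extend_chain(structure: Structure, full_sequence: str,
                 params: dict | None = None, relax_gaps: bool = True) -> Structure:
    """Fill in missing residues of a single chain in extended conformation.

    Existing residues must agree with `full_sequence` at their positions
    (1-based). Added residues get ideal covalent geometry; internal gaps are
    closed by a short covalent relaxation of only the added atoms.
    """
    from .sampling import _relax_added_atoms  # local import to avoid a cycle

    par = params or load_ideal_geometry()
    chain = structure.chain_ids[0]
    existing = {}
    for c, r, rn, span in structure.residue_spans():
        if r < 1 or r > len(full_sequence):
            raise ValueError(f"residue {r} outside the full sequence")
        want = AA1_TO_3[full_sequence[r - 1].upper()]
        if rn != want:
            raise ValueError(
                f"sequence mismatch at position {r}: structure has {rn}, sequence {want}")
        existing[r] = span
    missing = [r for r in range(1, len(full_sequence) + 1) if r not in existing]
    if not missing:
        return structure

    # group missing positions into contiguous gaps
    gaps = []
    cur = [missing[0]]
    for r in missing[1:]:
        if r == cur[-1] + 1:
            cur.append(r)
        else:
            gaps.append(cur)
            cur = [r]
    gaps.append(cur)

    def anchor_atoms(r):
        return tuple(structure.coords[structure.atom_index(r, nm, chain)]
                     for nm in ("N", "CA", "C"))

    def anchor_psi(r):
        """The anchor's psi implied by its carbonyl O (O sits at psi + pi)."""
        try:
            quad = np.array([[structure.atom_index(r, nm, chain)
                              for nm in ("N", "CA", "C", "O")]])
        except KeyError:
            return None
        return float(geometry.wrap_angle(
            geometry.dihedral_values(structure.coords, quad)[0] - np.pi))

    new_residues = {}
    internal_gap_positions = set()
    for gap in gaps:
        letters = [full_sequence[r - 1] for r in gap]
        before, after = gap[0] - 1, gap[-1] + 1
        if before in existing:
            placed = _grow_forward(par, anchor_atoms(before), letters, gap[0],
                                   chain, first_psi=anchor_psi(before))
            if after in existing:
                internal_gap_positions.update(gap)
        elif after in existing:
            placed = _grow_backward(par, anchor_atoms(after), letters, gap[-1], chain)
        else:
            raise ValueError("gap has no anchored neighbour residue")
        for r, resn, atoms in placed:
            new_residues[r] = (resn, atoms)

    chains, resis, resns, names, elems, coords, added_mask = [], [], [], [], [], [], []
    for r in range(1, len(full_sequence) + 1):
        if r in existing:
            for i in existing[r]:
                chains.append(chain); resis.append(r)
                resns.append(structure.res_names[i])
                names.append(structure.atom_names[i])
                elems.append(structure.elements[i])
                coords.append(structure.coords[i])
                added_mask.append(False)
        else:
            resn, atoms = new_residues[r]
            for nm, pos, el in atoms:
                chains.append(chain); resis.append(r)
                resns.append(resn); names.append(nm); elems.append(el)
                coords.append(pos); added_mask.append(True)
    out = Structure(chains, resis, resns, names, elems, np.array(coords))
    build_topology(out, par)
    added = np.flatnonzero(added_mask)
    if relax_gaps and internal_gap_positions:
        relax_idx = np.flatnonzero(
            np.asarray(added_mask) & np.isin(out.res_indices, sorted(internal_gap_positions)))
        _relax_added_atoms(out, relax_idx)
    # clash guard: added atoms vs pre-existing atoms
    if len(added) and len(added) < out.n_atoms:
        old = np.flatnonzero(~np.asarray(added_mask))
        d = np.linalg.norm(out.coords[added][:, None, :] - out.coords[old][None], axis=2)
        # ignore covalently bonded anchor contacts (peptide bond ~1.33 A)
        bonded = set(map(tuple, out.topology.bonds)) | set(
            map(tuple, out.topology.bonds[:, ::-1]))
        for ia, i in enumerate(added):
            for jo, j in enumerate(old):
                if (int(i), int(j)) in bonded:
                    d[ia, jo] = np.inf
        if d.min() < 1.5:
            _relax_added_atoms(out, added, repulsion=True)
    return out
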