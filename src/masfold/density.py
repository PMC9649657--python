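"""Density maps: simulation, I/O, real-space correlation and rigid docking.

Maps live on a cubic grid in a canonical axis order: ``grid[ix, iy, iz]``
with the physical position of a voxel center at ``origin + index * voxel``.
Files are MRC/CCP4 (MRC2014) read and written through gemmi; non-canonical
axis orderings on disk are normalized on read.

The Gaussian width convention for simulated density is
``sigma = resolution / (pi * sqrt(2))``, a common EM choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .structure import Structure


def sigma_from_resolution(resolution: float) -> float:
    return float(resolution) / (np.pi * np.sqrt(2.0))


@dataclass
class DensityMap:
    grid: np.ndarray           # (nx, ny, nz)
    voxel_size: float          # A
    origin: np.ndarray         # A triple, position of voxel (0,0,0)
    resolution: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.size == 0:
            raise ValueError("empty grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite")

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size,
                          self.origin.copy(), self.resolution)

    @property
    def shape(self):
        return self.grid.shape

    def extent(self):
        """(min_corner, max_corner) of voxel centers in Angstrom."""
        return (self.origin.copy(),
                self.origin + (np.array(self.grid.shape) - 1) * self.voxel_size)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points (0 outside)."""
        frac = (np.atleast_2d(points) - self.origin) / self.voxel_size
        return ndimage.map_coordinates(self.grid, frac.T, order=1, mode="constant")

    def integrated_density(self) -> float:
        return float(self.grid.sum() * self.voxel_size ** 3)


@dataclass
class Placement:
    rotation: np.ndarray       # proper 3x3
    translation: np.ndarray    # A triple
    score: float = np.nan      # cross-correlation in [-1, 1]

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if np.isfinite(self.score) and not (-1.0 - 1e-9 <= self.score <= 1.0 + 1e-9):
            raise ValueError("score must be a correlation in [-1, 1]")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "Placement":
        return Placement(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# simulation

def _gather_coords(structures, selection=None) -> np.ndarray:
    if isinstance(structures, Structure):
        structures = [structures]
    elif isinstance(structures, np.ndarray):
        return structures.reshape(-1, 3)
    blocks = []
    for s in structures:
        if isinstance(s, np.ndarray):
            blocks.append(s.reshape(-1, 3))
        else:
            idx = s.select(selection)
            if len(idx) == 0:
                raise ValueError("empty selection for map simulation")
            blocks.append(s.coords[idx])
    return np.vstack(blocks)


def simulate_map(structures, resolution: float, voxel_size: float,
                 selection=None, padding: float | None = None,
                 grid_like: DensityMap | None = None) -> DensityMap:
    """Sum of unit-integral isotropic atom Gaussians on a cubic grid.

    `structures` may be a Structure, a list of Structures, or raw (n,3)
    coordinates. With `grid_like`, density is accumulated on that map's
    grid (needed to correlate against it); otherwise the grid covers the
    atoms plus `padding` (default 2 x resolution).
    """
    if resolution < 2.0 * voxel_size:
        raise ValueError("resolution must be >= 2 x voxel_size (sampling)")
    coords = _gather_coords(structures, selection)
    sigma = sigma_from_resolution(resolution)
    if grid_like is not None:
        origin = grid_like.origin.copy()
        shape = np.array(grid_like.grid.shape)
        voxel_size = grid_like.voxel_size
    else:
        pad = 2.0 * resolution if padding is None else padding
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
        origin = lo
    grid = np.zeros(tuple(shape))
    ncut = int(np.ceil(3.5 * sigma / voxel_size))
    r = np.arange(-ncut, ncut + 1)
    offsets = np.stack(np.meshgrid(r, r, r, indexing="ij"), -1).reshape(-1, 3)
    norm = (2.0 * np.pi * sigma ** 2) ** -1.5
    base = np.rint((coords - origin) / voxel_size).astype(int)
    vox = base[:, None, :] + offsets[None, :, :]
    valid = np.all((vox >= 0) & (vox < shape), axis=2)
    pos = origin + vox * voxel_size
    diff = pos - coords[:, None, :]
    w = norm * np.exp(-np.einsum("amk,amk->am", diff, diff) / (2.0 * sigma ** 2))
    flat = np.ravel_multi_index(
        tuple(np.clip(vox[..., i], 0, shape[i] - 1) for i in range(3)), tuple(shape))
    np.add.at(grid.ravel(), flat[valid].ravel(), w[valid].ravel())
    return DensityMap(grid, voxel_size, origin, resolution)


# ---------------------------------------------------------------------------
# correlation

def cross_correlation(map_a: DensityMap, map_b: DensityMap,
                      mask: np.ndarray | str | None = None,
                      threshold_frac: float = 1e-4) -> float:
    """Pearson correlation of voxel values over a mask.

    Default mask: voxels where either map exceeds a small fraction of its
    maximum absolute value. ``mask="a"`` / ``mask="b"`` restrict to one
    map's support; a boolean array is used as-is.
    """
    if map_a.grid.shape != map_b.grid.shape or \
            abs(map_a.voxel_size - map_b.voxel_size) > 1e-9 or \
            not np.allclose(map_a.origin, map_b.origin, atol=1e-6):
        raise ValueError("maps must share grid shape, voxel size and origin")
    a, b = map_a.grid, map_b.grid
    if mask is None or isinstance(mask, str):
        ta = threshold_frac * np.abs(a).max()
        tb = threshold_frac * np.abs(b).max()
        if mask == "a":
            m = np.abs(a) > ta
        elif mask == "b":
            m = np.abs(b) > tb
        else:
            m = (np.abs(a) > ta) | (np.abs(b) > tb)
    else:
        m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty correlation mask")
    av = a[m] - a[m].mean()
    bv = b[m] - b[m].mean()
    denom = np.sqrt((av ** 2).sum() * (bv ** 2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((av * bv).sum() / denom, -1.0, 1.0))


def structure_map_cc(coords_or_structure, dmap: DensityMap,
                     resolution: float | None = None,
                     mask: str = "mobile") -> float:
    """CC between density simulated from coordinates and a target map.

    ``mask="mobile"`` correlates over the simulated density's own support
    (appropriate when the map holds several copies and we score one);
    ``mask="either"`` uses the symmetric default.
    """
    res = resolution or dmap.resolution
    if res is None:
        raise ValueError("no resolution available to simulate density")
    sim = simulate_map(coords_or_structure, res, dmap.voxel_size, grid_like=dmap)
    return cross_correlation(sim, dmap, mask="a" if mask == "mobile" else None)


# ---------------------------------------------------------------------------
# MRC I/O

def write_mrc(dmap: DensityMap, path) -> None:
    grid = gemmi.FloatGrid(*dmap.grid.shape)
    np.asarray(grid.array)[...] = dmap.grid.astype(np.float32)
    n = np.array(dmap.grid.shape)
    grid.set_unit_cell(gemmi.UnitCell(*(n * dmap.voxel_size), 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(val))
    if dmap.resolution is not None:
        # stash the stated resolution in an unused header slot (word 220)
        m.set_header_float(220, float(dmap.resolution))
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityMap:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to read MRC map {path}: {exc}") from exc
    m.setup(float("nan"))  # normalizes axis order to X, Y, Z
    arr = np.array(m.grid.array, dtype=float)
    sx, sy, sz = m.grid.spacing
    if not (abs(sx - sy) < 1e-4 * sx and abs(sx - sz) < 1e-4 * sx):
        raise ValueError("anisotropic voxels are not supported")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    res = m.header_float(220)
    res = float(res) if np.isfinite(res) and res > 0 else None
    arr = np.nan_to_num(arr, nan=0.0)
    return DensityMap(arr, float(sx), origin, res)


# ---------------------------------------------------------------------------
# rotation sampling

def uniform_rotations(n: int) -> np.ndarray:
    """Deterministic quasi-uniform SO(3) sample (super-Fibonacci spiral).

    Returns an (n, 3, 3) array of proper rotation matrices; seedless and
    reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    PHI = np.sqrt(2.0)
    PSI = 1.533751168755204288118041
    s = np.arange(n) + 0.5
    t = s / n
    r = np.sqrt(t)
    R = np.sqrt(1.0 - t)
    alpha = 2.0 * np.pi * s / PHI
    beta = 2.0 * np.pi * s / PSI
    quat = np.stack([r * np.sin(alpha), r * np.cos(alpha),
                     R * np.sin(beta), R * np.cos(beta)], axis=1)
    return Rotation.from_quat(quat).as_matrix()


# ---------------------------------------------------------------------------
# docking

def _radius_of_gyration(coords: np.ndarray) -> float:
    rel = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(rel ** 2, axis=1))))


def _cc_cropped(coords: np.ndarray, dmap: DensityMap, resolution: float) -> float:
    """CC over the simulated density's own support, computed on a cropped
    subgrid covering the atoms (identical to the full-grid value because the
    simulated support lies inside the crop)."""
    sigma = sigma_from_resolution(resolution)
    pad = 3.5 * sigma + 2.0 * dmap.voxel_size
    lo_idx = np.floor((coords.min(axis=0) - pad - dmap.origin) / dmap.voxel_size)
    hi_idx = np.ceil((coords.max(axis=0) + pad - dmap.origin) / dmap.voxel_size)
    shape = np.array(dmap.grid.shape)
    lo_idx = np.clip(lo_idx, 0, shape - 1).astype(int)
    hi_idx = np.clip(hi_idx, 0, shape - 1).astype(int)
    if np.any(hi_idx <= lo_idx):
        raise ValueError("structure does not overlap the map")
    sub = DensityMap(
        dmap.grid[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
                  lo_idx[2]:hi_idx[2] + 1].copy(),
        dmap.voxel_size, dmap.origin + lo_idx * dmap.voxel_size, dmap.resolution)
    sim = simulate_map(coords, resolution, dmap.voxel_size, grid_like=sub)
    return cross_correlation(sim, sub, mask="a")


def local_fit(structure, dmap: DensityMap, placement: Placement,
              resolution: float | None = None, maxfev: int = 250) -> Placement:
    """Local rigid-body refinement of a placement by coordinate ascent on CC.

    Optimizes the 6 rigid parameters (rotation about the placed centroid
    plus translation) with Powell's method; the returned score is never
    below the starting score.
    """
    coords = structure.coords if isinstance(structure, Structure) else np.asarray(structure)
    res = resolution or dmap.resolution
    if res is None:
        raise ValueError("no resolution available for density simulation")
    placed = placement.apply(coords)
    lo, hi = dmap.extent()
    if np.any(placed.max(axis=0) < lo) or np.any(placed.min(axis=0) > hi):
        raise ValueError("placement does not overlap the map")
    center = placed.mean(axis=0)
    rel = placed - center

    def params_to_coords(p):
        Rd = Rotation.from_rotvec(p[:3]).as_matrix()
        return rel @ Rd.T + center + p[3:]

    def objective(p):
        try:
            return -_cc_cropped(params_to_coords(p), dmap, res)
        except ValueError:
            return 1.0  # wandered off the map

    start_cc = -objective(np.zeros(6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # maxfev cutoff
        result = optimize.minimize(objective, np.zeros(6), method="Powell",
                                   options={"maxfev": maxfev, "xtol": 1e-3,
                                            "ftol": 1e-6})
    if -result.fun <= start_cc:
        return Placement(placement.rotation.copy(), placement.translation.copy(),
                         float(np.clip(start_cc, -1, 1)))
    p = result.x
    Rd = Rotation.from_rotvec(p[:3]).as_matrix()
    # compose: y = Rd (R x + t - c) + c + dt
    R_new = Rd @ placement.rotation
    t_new = Rd @ (placement.translation - center) + center + p[3:]
    return Placement(R_new, t_new, float(np.clip(-result.fun, -1, 1)))


def dock_positions(structure: Structure, dmap: DensityMap, n_positions: int,
                   rotation_samples: int = 2000, min_separation: float | None = None,
                   resolution: float | None = None, coarse_step: float | None = None,
                   refine: bool = True, candidate_factor: int = 3,
                   rotations_per_site: int = 4, maxfev: int = 250,
                   selection: str = "name CA") -> list[Placement]:
    """Multi-position rigid-body docking of one chain into a density map.

    A quasi-uniform rotation set crossed with a coarse translation grid is
    scored by mean interpolated density at (by default) CA positions; the
    best non-overlapping candidates are locally refined on full real-space
    CC and returned sorted by descending score with pairwise center-of-mass
    separation >= min_separation (non-max suppression).
    """
    res = resolution or dmap.resolution
    if res is None:
        raise ValueError("no resolution available for density simulation")
    sel = structure.select(selection)
    if len(sel) == 0:
        sel = np.arange(structure.n_atoms)
    probe = structure.coords[sel]
    centroid = structure.coords.mean(axis=0)
    rel = probe - centroid
    if min_separation is None:
        min_separation = _radius_of_gyration(structure.coords)
    step = coarse_step if coarse_step is not None else max(2.0 * dmap.voxel_size, 3.0)
    lo, hi = dmap.extent()
    axes = [np.arange(lo[i], hi[i] + 1e-9, step) for i in range(3)]
    trans = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)

    rots = uniform_rotations(rotation_samples)
    best_score = np.full(len(trans), -np.inf)
    best_rot = np.zeros(len(trans), dtype=int)
    for ir, R in enumerate(rots):
        pts = trans[:, None, :] + (rel @ R.T)[None, :, :]
        vals = dmap.interpolate(pts.reshape(-1, 3)).reshape(len(trans), -1)
        score = vals.mean(axis=1)
        upd = score > best_score
        best_score[upd] = score[upd]
        best_rot[upd] = ir

    order = np.argsort(best_score)[::-1]
    sites = []
    n_sites = candidate_factor * n_positions
    for idx in order:
        if not np.isfinite(best_score[idx]):
            continue
        c = trans[idx]
        if any(np.linalg.norm(c - prev) < min_separation for prev in sites):
            continue
        sites.append(c)
        if len(sites) >= n_sites:
            break

    # per shortlisted site, rescore every rotation and refine the top few:
    # pseudo-symmetric folds produce near-degenerate coarse scores for wrong
    # orientations, so a single rotation per site is not reliable
    per_site = min(rotations_per_site, rotation_samples)
    placements = []
    for c in sites:
        pts = c[None, None, :] + np.einsum("rij,aj->rai", rots, rel)
        vals = dmap.interpolate(pts.reshape(-1, 3)).reshape(len(rots), -1)
        top = np.argsort(vals.mean(axis=1))[::-1][:per_site]
        best_pl = None
        for ir in top:
            R = rots[ir]
            t = c - R @ centroid
            pl = Placement(R, t, np.nan)
            if refine:
                pl = local_fit(structure, dmap, pl, res, maxfev=maxfev)
            else:
                pl = Placement(R, t, structure_map_cc(
                    pl.apply(structure.coords), dmap, res, mask="mobile"))
            if best_pl is None or pl.score > best_pl.score:
                best_pl = pl
        placements.append(best_pl)

    placements.sort(key=lambda p: p.score, reverse=True)
    final: list[Placement] = []
    for pl in placements:
        com = pl.apply(structure.coords).mean(axis=0)
        if any(np.linalg.norm(com - f.apply(structure.coords).mean(axis=0))
               < min_separation for f in final):
            continue
        final.append(pl)
        if len(final) >= n_positions:
            break
    if len(final) < n_positions:
        warnings.warn(f"only {len(final)} of {n_positions} placements satisfy "
                      "the separation constraint")
    return final


def placements_to_tsv(placements: list[Placement], path) -> None:
    """Export placements as TSV: quaternion (x,y,z,w), translation, score."""
    import pandas as pd
    rows = []
    for pl in placements:
        q = Rotation.from_matrix(pl.rotation).as_quat()
        rows.append({"qx": q[0], "qy": q[1], "qz": q[2], "qw": q[3],
                     "tx": pl.translation[0], "ty": pl.translation[1],
                     "tz": pl.translation[2], "score": pl.score})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
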