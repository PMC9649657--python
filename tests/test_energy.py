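"""Energy terms: values on hand-computable cases and analytic gradients
against central finite differences."""

import numpy as np
import pytest

import masfold as mf
from masfold.energy import (CovalentTerm, DistanceRestraintTerm, GyrationTerm,
                            MapCCTerm, NCSTerm, System, TorsionRestraintTerm)
from masfold.restraints import CrossPeak, TorsionRestraint


def fd_check(term, coords, atol=1e-5, rtol=1e-3, h=1e-4, subset=None):
    """Central finite differences vs the analytic gradient."""
    grad = np.zeros_like(coords)
    term.evaluate(coords, grad)
    idx = subset if subset is not None else range(len(coords))
    for a in idx:
        for k in range(3):
            xp = coords.copy(); xp[a, k] += h
            xm = coords.copy(); xm[a, k] -= h
            num = (term.evaluate(xp) - term.evaluate(xm)) / (2 * h)
            assert grad[a, k] == pytest.approx(
                num, abs=atol, rel=rtol), f"atom {a} component {k}"


def single_restraint(i, ai, j, aj, extra=()):
    peak = CrossPeak("e", [(i, ai, j, aj), *extra])
    return mf.peaks_to_restraints([peak])


class TestDistanceTerm:
    def test_flat_bottom_zero_inside(self, toy_fold, fixture_restraints):
        term = DistanceRestraintTerm(fixture_restraints, toy_fold, k=30.0)
        grad = np.zeros_like(toy_fold.coords)
        e = term.evaluate(toy_fold.coords, grad)
        assert e == 0.0
        assert np.all(grad == 0.0)

    def test_quadratic_above_upper(self, toy_fold):
        rs = single_restraint(1, "CA", 20, "CA")
        term = DistanceRestraintTerm(rs, toy_fold, k=30.0)
        i = toy_fold.atom_index(1, "CA")
        j = toy_fold.atom_index(20, "CA")
        coords = toy_fold.coords.copy()
        # place the pair at exactly upper bound + 0.5 A
        direction = coords[j] - coords[i]
        coords[j] = coords[i] + direction / np.linalg.norm(direction) * (7.2 + 0.5)
        assert term.evaluate(coords) == pytest.approx(30.0 * 0.25)  # 7.5

    def test_r6_sum_dominated_by_short_pair(self):
        d_eff = (4.0 ** -6 + 20.0 ** -6) ** (-1 / 6)
        assert d_eff == pytest.approx(4.0, abs=1e-3)
        # a two-candidate ambiguous restraint with one satisfied pair costs 0
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 20.0, 0], [0, 0, 0]])
        term = DistanceRestraintTerm.from_arrays(
            pair_i=[0, 2], pair_j=[1, 3], rid=[0, 0],
            lower=[2.0], upper=[7.2], k=30.0)
        assert term.effective_distances(coords)[0] == pytest.approx(d_eff)
        assert term.evaluate(coords) == 0.0

    def test_below_lower_bound(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        term = DistanceRestraintTerm.from_arrays([0], [1], [0], [2.0], [7.2],
                                                 k=10.0)
        assert term.evaluate(coords) == pytest.approx(10.0 * 1.0 ** 2)

    def test_unresolvable_atom(self, toy_fold):
        rs = single_restraint(1, "CZ", 2, "CA")
        with pytest.raises(KeyError, match="restraint 0"):
            DistanceRestraintTerm(rs, toy_fold)

    def test_gradient(self, rng):
        coords = rng.normal(scale=3.0, size=(8, 3))
        term = DistanceRestraintTerm.from_arrays(
            pair_i=[0, 2, 4, 5], pair_j=[1, 3, 6, 7], rid=[0, 0, 1, 2],
            lower=[2.0, 2.0, 2.0], upper=[3.0, 3.5, 2.5], k=7.0)
        fd_check(term, coords)


class TestTorsionTerm:
    def test_zero_at_target(self, toy_fold, fixture_a):
        term = TorsionRestraintTerm(fixture_a["torsions"], toy_fold, k=200.0)
        assert term.evaluate(toy_fold.coords) == 0.0

    def test_periodic_wrap(self, toy_fold):
        tors = [TorsionRestraint(5, "phi", -60.0 + 360.0, tolerance=1e-9)]
        term = TorsionRestraintTerm(tors, toy_fold, k=200.0)
        assert term.evaluate(toy_fold.coords) == pytest.approx(0.0, abs=1e-6)

    def test_known_penalty(self):
        # |delta| - tol = 0.1 rad at k = 200 -> 2.0 kcal/mol
        coords = np.array([[1.0, 1, 0], [0.0, 0, 0], [1.0, 0, 0],
                           [1.5, -0.5, 0.8]])
        term = TorsionRestraintTerm.from_arrays([[0, 1, 2, 3]], [0.0], [0.0],
                                                k=200.0)
        from masfold.geometry import dihedral_values
        phi = dihedral_values(coords, np.array([[0, 1, 2, 3]]))[0]
        term.targets = np.array([phi - 0.1])
        assert term.evaluate(coords) == pytest.approx(2.0, rel=1e-6)

    def test_collinear_raises(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        term = TorsionRestraintTerm.from_arrays([[0, 1, 2, 3]], [0.0], [0.1])
        grad = np.zeros_like(coords)
        with pytest.raises(ValueError, match="degenerate"):
            term.evaluate(coords, grad)

    def test_gradient(self, rng):
        coords = rng.normal(scale=2.0, size=(6, 3))
        term = TorsionRestraintTerm.from_arrays(
            [[0, 1, 2, 3], [1, 2, 3, 4], [2, 3, 4, 5]],
            [0.5, -2.0, 3.0], [0.05, 0.1, 0.0], k=11.0)
        fd_check(term, coords)


class TestCovalentTerm:
    def test_zero_at_ideal(self, toy_fold):
        term = CovalentTerm(toy_fold.topology)
        assert term.evaluate(toy_fold.coords) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_stretch(self, toy_fold):
        term = CovalentTerm(toy_fold.topology)
        i, j = toy_fold.topology.bonds[0]
        energies = []
        for stretch in (0.0, 0.05, 0.1, 0.2):
            coords = toy_fold.coords.copy()
            d = coords[j] - coords[i]
            coords[j] += stretch * d / np.linalg.norm(d)
            energies.append(term.evaluate(coords))
        assert all(b > a for a, b in zip(energies, energies[1:]))

    def test_gradient(self, toy_fold, rng):
        term = CovalentTerm(toy_fold.topology)
        coords = toy_fold.coords + rng.normal(0, 0.05, toy_fold.coords.shape)
        fd_check(term, coords, subset=range(0, 30, 3), atol=1e-3, rtol=1e-3)


class TestNCSTerm:
    def _two_groups(self, rng, n=12):
        a = rng.normal(scale=4.0, size=(n, 3))
        return a

    def test_identical_subunits_zero(self, rng):
        a = self._two_groups(rng)
        coords = np.vstack([a, a.copy()])
        term = NCSTerm([np.arange(12), np.arange(12, 24)], tolerance=1.0, k=10)
        assert term.evaluate(coords) == 0.0

    def test_rigid_motion_free(self, rng):
        from scipy.spatial.transform import Rotation
        a = self._two_groups(rng)
        R = Rotation.from_rotvec([0.5, 1.0, -0.2]).as_matrix()
        coords = np.vstack([a, a @ R.T + [10.0, 0, 0]])
        term = NCSTerm([np.arange(12), np.arange(12, 24)], tolerance=1.0, k=10)
        assert term.evaluate(coords) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_excess(self, rng):
        # scaling about the centroid gives an exactly known superposed RMSD
        a = self._two_groups(rng)
        c = a.mean(0)
        rg = np.sqrt(np.mean(np.sum((a - c) ** 2, axis=1)))
        s = 1.0 + 1.5 / rg
        b = c + s * (a - c)
        coords = np.vstack([a, b])
        term = NCSTerm([np.arange(12), np.arange(12, 24)], tolerance=1.0, k=10)
        assert term.pair_rmsds(coords)[0] == pytest.approx(1.5, abs=1e-9)
        assert term.evaluate(coords) == pytest.approx(10.0 * 0.25, rel=1e-6)

    def test_gradient(self, rng):
        a = self._two_groups(rng)
        b = a + rng.normal(0, 0.8, a.shape)
        coords = np.vstack([a, b])
        term = NCSTerm([np.arange(12), np.arange(12, 24)], tolerance=0.2, k=5)
        fd_check(term, coords, atol=1e-4, rtol=2e-3)

    def test_mismatched_sizes(self):
        with pytest.raises(ValueError):
            NCSTerm([np.arange(5), np.arange(5, 12)])


class TestMapTerm:
    def _term(self, structure, k=50.0, selection="backbone"):
        idx = structure.select(selection)
        dmap = mf.simulate_map(structure.coords[idx], 8.0, 2.0)
        return MapCCTerm(dmap, idx, k=k), dmap

    def test_zero_at_perfect_fit(self, toy_fold):
        term, _ = self._term(toy_fold)
        e = term.evaluate(toy_fold.coords)
        assert e == pytest.approx(0.0, abs=1e-6)
        assert term.cc(toy_fold.coords) == pytest.approx(1.0, abs=1e-6)

    def test_bounded(self, toy_fold, rng):
        term, _ = self._term(toy_fold, k=50.0)
        coords = toy_fold.coords + rng.normal(0, 5.0, toy_fold.coords.shape)
        e = term.evaluate(coords)
        assert 0.0 <= e <= 100.0

    def test_unselected_atoms_zero_gradient(self, toy_fold):
        idx = toy_fold.select("backbone and resi 1-20")
        dmap = mf.simulate_map(toy_fold.coords[idx], 8.0, 2.0)
        term = MapCCTerm(dmap, idx, k=50.0)
        grad = np.zeros_like(toy_fold.coords)
        coords = toy_fold.coords + 0.5
        term.evaluate(coords, grad)
        excluded = np.setdiff1d(np.arange(toy_fold.n_atoms), idx)
        assert np.all(grad[excluded] == 0.0)
        assert np.any(grad[idx] != 0.0)

    def test_residue_mask_restricts_contributions(self, toy_fold):
        masked = toy_fold.select("backbone and resi 1-10,15-25")
        dmap = mf.simulate_map(toy_fold, 8.0, 2.0)
        term = MapCCTerm(dmap, masked, k=50.0)
        assert set(term.atom_indices()) == set(masked)

    def test_out_of_map(self, toy_fold):
        term, _ = self._term(toy_fold)
        with pytest.raises(mf.OutOfMapError):
            term.evaluate(toy_fold.coords + 500.0)

    def test_gradient(self, toy_fold, rng):
        term, _ = self._term(toy_fold)
        coords = toy_fold.coords + rng.normal(0, 1.0, toy_fold.coords.shape)
        fd_check(term, coords, subset=list(toy_fold.select("backbone"))[:8],
                 atol=1e-6, rtol=2e-3)


class TestHbondTerm:
    def test_helix_satisfies_default_pairs(self):
        st, _ = mf.make_toy_fold(15, "helix", seed=0)
        term = mf.backbone_hbond_term(st)
        assert term.name == "hbond"
        # ideal-helix O(i)...N(i+4) distances sit inside the flat bottom
        assert term.evaluate(st.coords) == pytest.approx(0.0, abs=1e-9)

    def test_extended_chain_penalized(self):
        st, _ = mf.make_toy_fold(15, "strand", seed=0)
        term = mf.backbone_hbond_term(st)
        assert term.evaluate(st.coords) > 0.0


class TestSystem:
    def test_all_disabled_zero(self, toy_fold, fixture_restraints):
        term = DistanceRestraintTerm(fixture_restraints, toy_fold, k=30.0)
        system = System(toy_fold, [term])
        bd = mf.total_energy(system, weights={"distance": 0})
        assert bd.total == 0.0

    def test_additivity(self, toy_fold, fixture_a, fixture_restraints, rng):
        st = toy_fold
        terms = [DistanceRestraintTerm(fixture_restraints, st, k=30.0),
                 TorsionRestraintTerm(fixture_a["torsions"], st, k=200.0),
                 CovalentTerm(st.topology)]
        system = System(st, terms)
        coords = st.coords + rng.normal(0, 0.3, st.coords.shape)
        bd = system.energy(coords)
        individual = sum(t.evaluate(coords) for t in terms)
        assert bd.total == pytest.approx(individual, rel=1e-10)

    def test_gyration_disabled_with_map(self, toy_fold):
        idx = toy_fold.select("backbone")
        dmap = mf.simulate_map(toy_fold.coords[idx], 8.0, 2.0)
        system = System(toy_fold, [GyrationTerm(5.0, idx, k=1.0),
                                   MapCCTerm(dmap, idx, k=50.0)])
        assert not system.term("gyration").enabled
        assert system.term("map").enabled
        # and in the reverse insertion order
        system2 = System(toy_fold, [MapCCTerm(dmap, idx, k=50.0),
                                    GyrationTerm(5.0, idx, k=1.0)])
        assert not system2.term("gyration").enabled
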