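"""Structure I/O, superposition, ensemble statistics and chain building."""

import numpy as np
import pytest
from scipy.optimize import minimize as sp_minimize
from scipy.spatial.transform import Rotation

import masfold as mf
from masfold.structure import Topology, build_topology, infer_element


def tiny_chain(n=3, seed=0):
    st, _ = mf.make_toy_fold(max(n, 5), "helix", seed=seed)
    return st


class TestIO:
    def test_pdb_roundtrip(self, tmp_path):
        st = tiny_chain()
        path = tmp_path / "toy.pdb"
        mf.write_structure(st, path)
        back = mf.read_structure(path)
        assert np.all(back.atom_names == st.atom_names)
        assert np.all(back.res_indices == st.res_indices)
        assert np.allclose(back.coords, st.coords, atol=1.5e-3)  # PDB precision
        # writing what was read reproduces it exactly
        path2 = tmp_path / "toy2.pdb"
        mf.write_structure(back, path2)
        again = mf.read_structure(path2)
        assert np.array_equal(again.coords, back.coords)

    def test_mmcif_roundtrip(self, tmp_path):
        st = tiny_chain()
        path = tmp_path / "toy.cif"
        mf.write_structure(st, path, fmt="mmcif")
        back = mf.read_structure(path, fmt="mmcif")
        assert np.all(back.atom_names == st.atom_names)
        assert np.allclose(back.coords, st.coords, atol=1.5e-3)

    def test_multimodel_ensemble(self, tmp_path):
        st = tiny_chain()
        members = []
        for k in range(4):
            m = st.copy()
            m.coords = st.coords + k
            members.append(m)
        path = tmp_path / "ens.pdb"
        mf.write_structure(members, path)
        back = mf.read_ensemble(path)
        assert len(back) == 4

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            mf.read_structure("/nonexistent/file.pdb")

    def test_malformed_pdb(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("ATOM   garbage line that is not parseable\n" * 3)
        with pytest.raises(ValueError):
            mf.read_structure(bad)

    def test_element_inference(self, tmp_path):
        # hand-built PDB records without the element column
        lines = [
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00",
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00",
            "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00",
            "ATOM      4  O   ALA A   1       3.100   1.500   0.600  1.00  0.00",
            "ATOM      5  CB  ALA A   1       2.000  -1.000   1.000  1.00  0.00",
            "END",
        ]
        path = tmp_path / "noelem.pdb"
        path.write_text("\n".join(lines) + "\n")
        st = mf.read_structure(path)
        assert list(st.elements) == ["N", "C", "C", "O", "C"]

    @pytest.mark.parametrize("name,element", [
        ("CA", "C"), ("CB", "C"), ("N", "N"), ("O", "O"), ("OG1", "O"),
        ("SD", "S"), ("1HB", "H"), ("NE2", "N"),
    ])
    def test_infer_element_rules(self, name, element):
        assert infer_element(name) == element


class TestSelection:
    def test_backbone_and_range(self, toy_fold):
        idx = toy_fold.select("backbone and resi 5-10")
        assert len(idx) == 4 * 6
        assert set(toy_fold.atom_names[idx]) == {"N", "CA", "C", "O"}

    def test_name_list(self, toy_fold):
        idx = toy_fold.select("name CA,CB")
        assert set(toy_fold.atom_names[idx]) <= {"CA", "CB"}

    def test_unknown_token(self, toy_fold):
        with pytest.raises(ValueError):
            toy_fold.select("sidechain")


class TestSuperpose:
    def test_identical(self, toy_fold):
        res = mf.superpose(toy_fold, toy_fold)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_recovered(self, toy_fold, rng):
        R = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        mobile = toy_fold.copy()
        mobile.coords = toy_fold.coords @ R.T + [5.0, -3.0, 8.0]
        res = mf.superpose(toy_fold, mobile)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        moved = res.apply(mobile.coords)
        assert np.allclose(moved, toy_fold.coords, atol=1e-8)

    def test_rmsd_symmetry(self, toy_fold, rng):
        mobile = toy_fold.copy()
        mobile.coords = toy_fold.coords + rng.normal(0, 1, toy_fold.coords.shape)
        r_ab = mf.superpose(toy_fold, mobile).rmsd
        r_ba = mf.superpose(mobile, toy_fold).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-6)

    def test_degenerate_selection(self):
        st = tiny_chain()
        collinear = st.copy()
        collinear.coords = np.outer(np.arange(st.n_atoms), [1.0, 0, 0])
        with pytest.raises(ValueError):
            mf.superpose(collinear, collinear)

    def test_matches_quaternion_grid_oracle(self, rng):
        """Kabsch result equals brute-force minimization over rotations."""
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))

        def rmsd_for_rotvec(rv):
            R = Rotation.from_rotvec(rv).as_matrix()
            A = Q - Q.mean(0)
            B = P - P.mean(0)
            return np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1)))

        # coarse quaternion grid, then local refinement
        grid = Rotation.random(4000, random_state=1).as_rotvec()
        best = min(grid, key=rmsd_for_rotvec)
        res = sp_minimize(rmsd_for_rotvec, best, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 5000})
        sa = mf.Structure(["A"] * 10, range(1, 11), ["ALA"] * 10, ["CA"] * 10,
                          ["C"] * 10, P)
        sb = mf.Structure(["A"] * 10, range(1, 11), ["ALA"] * 10, ["CA"] * 10,
                          ["C"] * 10, Q)
        assert mf.superpose(sa, sb).rmsd == pytest.approx(res.fun, abs=1e-4)


class TestEnsembleRmsd:
    def test_identical_copies(self, toy_fold):
        mean, sd, mat = mf.pairwise_ensemble_rmsd([toy_fold.copy()
                                                   for _ in range(4)])
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_two_members(self, toy_fold, rng):
        other = toy_fold.copy()
        other.coords = toy_fold.coords + rng.normal(0, 0.5, toy_fold.coords.shape)
        mean, sd, mat = mf.pairwise_ensemble_rmsd([toy_fold, other])
        assert mean == pytest.approx(mat[0, 1])
        assert sd == 0.0

    def test_rigid_motion_invariance(self, toy_fold, rng):
        members = []
        for k in range(3):
            m = toy_fold.copy()
            m.coords = toy_fold.coords + rng.normal(0, 0.3, toy_fold.coords.shape)
            members.append(m)
        mean0, _, _ = mf.pairwise_ensemble_rmsd(members)
        R = Rotation.from_rotvec([0.4, -0.2, 1.1]).as_matrix()
        members[1].coords = members[1].coords @ R.T + [20.0, 0.0, -7.0]
        mean1, _, _ = mf.pairwise_ensemble_rmsd(members)
        assert mean1 == pytest.approx(mean0, abs=1e-9)

    def test_mismatch_error_names_atom(self, toy_fold):
        other = toy_fold.copy()
        other.atom_names[5] = "XX"
        with pytest.raises(ValueError, match="XX"):
            mf.pairwise_ensemble_rmsd([toy_fold, other])

    def test_needs_two(self, toy_fold):
        with pytest.raises(ValueError):
            mf.pairwise_ensemble_rmsd([toy_fold])


class TestGeometryDeviations:
    def test_ideal_is_zero(self, toy_fold):
        b, a, i = mf.geometry_deviations(toy_fold)
        assert b == pytest.approx(0.0, abs=1e-6)
        assert a == pytest.approx(0.0, abs=1e-6)
        assert i == pytest.approx(0.0, abs=1e-6)

    def test_single_stretched_bond(self):
        # 4 ideal bonds of 1.5 A in a straight chain; stretch one by 0.02
        coords = np.array([[1.5 * k, 0.0, 0.0] for k in range(5)])
        coords[4, 0] += 0.02
        st = mf.Structure(["A"] * 5, range(1, 6), ["GLY"] * 5, ["CA"] * 5,
                          ["C"] * 5, coords)
        st.topology = Topology(
            np.array([[k, k + 1] for k in range(4)]), np.full(4, 1.5),
            np.empty((0, 3), int), np.empty(0),
            np.empty((0, 4), int), np.empty(0))
        b, _, _ = mf.geometry_deviations(st)
        assert b == pytest.approx(0.01)

    def test_rigid_motion_invariance(self, toy_fold):
        moved = toy_fold.copy()
        R = Rotation.from_rotvec([1.0, 0.3, -0.7]).as_matrix()
        moved.coords = toy_fold.coords @ R.T + [3.0, 4.0, 5.0]
        assert np.allclose(mf.geometry_deviations(moved),
                           mf.geometry_deviations(toy_fold), atol=1e-9)

    def test_empty_topology_errors(self, toy_fold):
        st = toy_fold.copy()
        st.topology = None
        with pytest.raises(ValueError):
            mf.geometry_deviations(st)


def _subset(structure, resi_lo, resi_hi):
    idx = structure.select(f"resi {resi_lo}-{resi_hi}")
    sub = mf.Structure(structure.chain_ids[idx], structure.res_indices[idx],
                       structure.res_names[idx], structure.atom_names[idx],
                       structure.elements[idx], structure.coords[idx])
    return sub


class TestExtendChain:
    def test_nothing_missing(self, toy_fold):
        out = mf.extend_chain(toy_fold, toy_fold.sequence)
        assert out.n_atoms == toy_fold.n_atoms
        assert np.allclose(out.coords, toy_fold.coords)

    def test_c_terminal_extension(self):
        full, _ = mf.make_toy_fold(40, "helix", seed=1)
        seq = full.sequence
        truncated = _subset(full, 1, 29)
        out = mf.extend_chain(truncated, seq)
        assert out.n_residues == 40
        # the added span alone has ideal covalent geometry
        added = _subset(out, 30, 40)
        build_topology(added)
        assert np.allclose(mf.geometry_deviations(added), 0.0, atol=1e-6)
        # and does not clash with the pre-existing atoms
        new = out.select("resi 30-40")
        old = out.select("resi 1-29")
        d = np.linalg.norm(out.coords[new][:, None] - out.coords[old][None],
                           axis=2)
        assert np.sort(d.ravel())[1] >= 1.5  # only the peptide bond is closer

    def test_internal_gap_closed(self):
        full, _ = mf.make_toy_fold(20, "helix", seed=2)
        seq = full.sequence
        have = np.concatenate([full.select("resi 1-9"), full.select("resi 11-20")])
        partial = mf.Structure(full.chain_ids[have], full.res_indices[have],
                               full.res_names[have], full.atom_names[have],
                               full.elements[have], full.coords[have])
        out = mf.extend_chain(partial, seq)
        assert out.n_residues == 20
        # peptide bonds around the rebuilt residue are restored
        c9 = out.coords[out.atom_index(9, "C")]
        n10 = out.coords[out.atom_index(10, "N")]
        c10 = out.coords[out.atom_index(10, "C")]
        n11 = out.coords[out.atom_index(11, "N")]
        assert np.linalg.norm(n10 - c9) == pytest.approx(1.33, abs=0.05)
        assert np.linalg.norm(n11 - c10) == pytest.approx(1.33, abs=0.05)
        # no clash of the rebuilt residue against existing atoms
        added = out.select("resi 10")
        others = np.setdiff1d(np.arange(out.n_atoms), added)
        d = np.linalg.norm(out.coords[added][:, None] - out.coords[others][None],
                           axis=2)
        assert d.min() > 1.2  # bonded neighbours ~1.33; nothing closer

    def test_sequence_mismatch_names_position(self, toy_fold):
        seq = list(toy_fold.sequence)
        seq[4] = "W" if seq[4] != "W" else "G"
        with pytest.raises(ValueError, match="position 5"):
            mf.extend_chain(toy_fold, "".join(seq))


class TestReplicate:
    def test_single_copy(self, toy_fold):
        asm = mf.replicate_subunits(toy_fold, 1)
        assert asm.n_subunits == 1
        assert np.allclose(asm.subunits[0].coords, toy_fold.coords)

    def test_22_subunits(self, toy_fold):
        ids = [chr(ord("A") + i) for i in range(22)]
        asm = mf.replicate_subunits(toy_fold, 22, ids)
        assert asm.segment_ids == ids
        assert all(s.n_atoms == toy_fold.n_atoms for s in asm.subunits)
        combined = asm.to_structure()
        assert combined.n_atoms == 22 * toy_fold.n_atoms
        assert set(combined.chain_ids) == set(ids)

    def test_deep_copy(self, toy_fold):
        asm = mf.replicate_subunits(toy_fold, 3)
        asm.subunits[0].coords += 100.0
        assert np.allclose(asm.subunits[1].coords, toy_fold.coords)

    def test_duplicate_ids(self, toy_fold):
        with pytest.raises(ValueError):
            mf.replicate_subunits(toy_fold, 2, ["A", "A"])
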