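import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensembleproj.structures import (
    AtomKey,
    CoordinateMatrix,
    Structure,
    build_matrix,
    common_atom_set,
    kabsch_rotation,
    read_calpha,
    read_matrix,
    superpose_ensemble,
    write_matrix,
)

from conftest import make_structure, random_rigid_transform


class TestReadCalpha:
    def test_minimal_fixture_parses_three_ca(self, minimal_pdb):
        s = read_calpha(minimal_pdb)
        assert len(s) == 3
        assert s.keys() == [AtomKey("A", 1, ""), AtomKey("A", 2, ""), AtomKey("A", 3, "")]
        np.testing.assert_allclose(s.atoms[AtomKey("A", 3, "")], [1.0, 2.0, 3.5])

    def test_non_ca_atoms_ignored(self, minimal_pdb):
        s = read_calpha(minimal_pdb)
        assert not any(np.allclose(v, [9.0, 9.0, 9.0]) for v in s.atoms.values())

    def test_altloc_reject_raises(self, altloc_pdb):
        with pytest.raises(ValueError, match="alternate locations"):
            read_calpha(altloc_pdb, altloc_policy="reject")

    def test_altloc_highest_occupancy_takes_b(self, altloc_pdb):
        # hand-checked: altLoc A occ 0.40 at x=1, altLoc B occ 0.60 at x=2
        s = read_calpha(altloc_pdb, altloc_policy="highest_occupancy")
        np.testing.assert_allclose(s.atoms[AtomKey("A", 1, "")], [2.0, 0.0, 0.0])

    def test_altloc_take_first(self, altloc_pdb):
        s = read_calpha(altloc_pdb, altloc_policy="take_first")
        np.testing.assert_allclose(s.atoms[AtomKey("A", 1, "")], [1.0, 0.0, 0.0])

    def test_occupancy_tie_broken_by_altloc_letter(self, tmp_path):
        text = (
            "ATOM      1  CA BALA A   1       5.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA AALA A   1       6.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      3  CA  GLY A   2       0.000   3.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  SER A   3       0.000   0.000   5.000  1.00  0.00           C\n"
        )
        path = tmp_path / "tie.pdb"
        path.write_text(text)
        s = read_calpha(path, altloc_policy="highest_occupancy")
        np.testing.assert_allclose(s.atoms[AtomKey("A", 1, "")], [6.0, 0.0, 0.0])

    def test_no_ca_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("ATOM      1  N   ALA A   1       0.0     0.0     0.0  1.00  0.00\n")
        with pytest.raises(ValueError, match="no CA"):
            read_calpha(path)

    def test_chain_filter(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       2.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   3       3.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  ALA B   1       0.000   1.000   0.000  1.00  0.00           C\n"
            "ATOM      5  CA  ALA B   2       0.000   2.000   0.000  1.00  0.00           C\n"
            "ATOM      6  CA  ALA B   3       0.000   3.000   0.000  1.00  0.00           C\n"
        )
        path = tmp_path / "two_chains.pdb"
        path.write_text(text)
        s = read_calpha(path, chain_filter={"A"})
        assert {k.chain_id for k in s.atoms} == {"A"}

    def test_only_first_model_used(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       2.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   3       3.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      4  CA  ALA A   1      99.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        path = tmp_path / "models.pdb"
        path.write_text(text)
        s = read_calpha(path)
        assert len(s) == 3
        np.testing.assert_allclose(s.atoms[AtomKey("A", 1, "")], [1.0, 0.0, 0.0])


class TestCommonAtomSet:
    def test_identical_structures_full_list(self, toy_coords):
        a = make_structure("a", toy_coords)
        b = make_structure("b", toy_coords)
        assert common_atom_set([a, b]) == a.keys()

    def test_overlapping_ranges(self):
        coords = np.arange(36, dtype=float).reshape(12, 3)
        a = Structure("a", {AtomKey("A", i, ""): coords[i - 1] for i in range(1, 11)})
        b = Structure("b", {AtomKey("A", i, ""): coords[i - 3] for i in range(3, 13)})
        keys = common_atom_set([a, b])
        assert keys == [AtomKey("A", i, "") for i in range(3, 11)]

    def test_shared_set_of_565_over_58_structures(self):
        rng = np.random.default_rng(0)
        base = {AtomKey("A", i, ""): rng.normal(size=3) for i in range(1, 601)}
        structures = []
        for j in range(58):
            atoms = dict(base)
            # each entry is missing a few residues outside the core 1..565
            for drop in range(566 + (j % 35), 601):
                atoms.pop(AtomKey("A", drop, ""), None)
            structures.append(Structure(f"s{j}", atoms))
        structures.append(Structure("core", {k: v for k, v in base.items() if k.residue_number <= 565}))
        assert len(common_atom_set(structures)) == 565

    def test_empty_intersection_names_culprit(self):
        coords = np.arange(30, dtype=float).reshape(10, 3)
        a = Structure("first", {AtomKey("A", i, ""): coords[i] for i in range(5)})
        b = Structure("second", {AtomKey("B", i, ""): coords[i] for i in range(5)})
        with pytest.raises(ValueError, match="second"):
            common_atom_set([a, b])

    def test_requires_two_structures(self, toy_structure):
        with pytest.raises(ValueError):
            common_atom_set([toy_structure])


class TestSuperposition:
    def test_exact_recovery_of_rigid_transform(self, toy_coords):
        rng = np.random.default_rng(3)
        rot, t = random_rigid_transform(rng)
        a = make_structure("a", toy_coords)
        b = make_structure("b", toy_coords @ rot.T + t)
        keys = a.keys()
        fitted = superpose_ensemble([a, b], keys)
        rmsd = np.sqrt(np.mean((fitted[0].coords(keys) - fitted[1].coords(keys)) ** 2))
        assert rmsd < 1e-10

    def test_self_superposition_identity(self, toy_coords):
        a = make_structure("a", toy_coords)
        b = make_structure("b", toy_coords)
        fitted = superpose_ensemble([a, b], a.keys(), reference="first")
        centered = toy_coords - toy_coords.mean(axis=0)
        np.testing.assert_allclose(fitted[1].coords(a.keys()), centered, atol=1e-10)

    def test_mirror_image_no_reflection(self):
        # 4-atom chiral toy; brute-force search over proper rotations is the oracle
        pts = np.array(
            [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [3.8, 3.8, 0.0], [3.8, 3.8, 3.8]]
        )
        mirror = pts * np.array([1.0, 1.0, -1.0])
        a = make_structure("a", pts)
        b = make_structure("b", mirror)
        keys = a.keys()
        fitted = superpose_ensemble([a, b], keys, reference="first")
        diff = fitted[1].coords(keys) - fitted[0].coords(keys)
        rmsd = np.sqrt(np.mean(diff**2))
        assert rmsd > 0.1  # mirror image cannot be recovered

        # oracle: dense sampling of proper rotations cannot beat the fit
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(11)
        target = pts - pts.mean(axis=0)
        mob = mirror - mirror.mean(axis=0)
        best = np.inf
        for rot in Rotation.random(4000, rng=rng):
            cand = mob @ rot.as_matrix().T
            best = min(best, np.sqrt(np.mean((cand - target) ** 2)))
        assert rmsd <= best + 1e-6

        rotmat = kabsch_rotation(mob, target)
        assert np.linalg.det(rotmat) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_contract_preserves_internal_distances(self):
        rng = np.random.default_rng(5)
        coords = [rng.normal(scale=6.0, size=(20, 3)) for _ in range(4)]
        structures = [make_structure(f"s{i}", c) for i, c in enumerate(coords)]
        keys = structures[0].keys()
        fitted = superpose_ensemble(structures, keys)
        for before, after in zip(structures, fitted):
            xb, xa = before.coords(keys), after.coords(keys)
            db = np.linalg.norm(xb[:, None] - xb[None], axis=-1)
            da = np.linalg.norm(xa[:, None] - xa[None], axis=-1)
            np.testing.assert_allclose(da, db, atol=1e-9)

    def test_underdetermined_raises(self, toy_coords):
        a = make_structure("a", toy_coords)
        b = make_structure("b", toy_coords)
        with pytest.raises(ValueError, match="underdetermined|>= 3"):
            superpose_ensemble([a, b], a.keys()[:2])


class TestBuildMatrix:
    def test_shape_58_by_1695(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(565, 3))
        structures = [
            make_structure(f"s{i}", base + rng.normal(scale=0.1, size=base.shape))
            for i in range(58)
        ]
        keys = common_atom_set(structures)
        matrix = build_matrix(structures, keys)
        assert matrix.shape == (58, 1695)

    def test_shape_78_by_1608(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(536, 3))
        structures = [make_structure(f"s{i}", base) for i in range(78)]
        matrix = build_matrix(structures, common_atom_set(structures))
        assert matrix.shape == (78, 1608)

    def test_single_atom_rows(self):
        a = Structure(
            "a",
            {
                AtomKey("A", 1, ""): np.zeros(3),
                AtomKey("A", 2, ""): np.ones(3),
                AtomKey("A", 3, ""): 2 * np.ones(3),
            },
        )
        b = Structure(
            "b",
            {
                AtomKey("A", 1, ""): np.array([1.0, 0.0, 0.0]),
                AtomKey("A", 2, ""): np.ones(3),
                AtomKey("A", 3, ""): 2 * np.ones(3),
            },
        )
        m = build_matrix([a, b], [AtomKey("A", 1, "")])
        np.testing.assert_allclose(m.values, [[0, 0, 0], [1, 0, 0]])

    def test_missing_key_raises(self, toy_coords):
        a = make_structure("a", toy_coords)
        b = make_structure("b", toy_coords, chain="B")
        with pytest.raises(KeyError):
            build_matrix([a, b], a.keys())


class TestMatrixRoundTrip:
    def test_round_trip(self, tmp_path, toy_coords):
        structures = [make_structure(f"s{i}", toy_coords + i) for i in range(3)]
        keys = structures[0].keys()
        matrix = build_matrix(structures, keys)
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        back = read_matrix(path)
        assert back.row_labels == matrix.row_labels
        assert back.atom_keys == matrix.atom_keys
        np.testing.assert_allclose(back.values, matrix.values, atol=1e-6)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip_random_values(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(scale=100.0, size=(3, 9))
        keys = [AtomKey("A", i, "") for i in range(1, 4)]
        matrix = CoordinateMatrix(values, ["a", "b", "c"], keys)
        path = tmp_path_factory.mktemp("rt") / "m.tsv"
        write_matrix(matrix, path)
        np.testing.assert_allclose(read_matrix(path).values, values, atol=1e-6)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_matrix(path)

    def test_non_numeric_cell_names_location(self, tmp_path, toy_coords):
        structures = [make_structure(f"s{i}", toy_coords) for i in range(2)]
        matrix = build_matrix(structures, structures[0].keys())
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        lines = path.read_text().splitlines()
        cells = lines[1].split("\t")
        cells[3] = "oops"
        lines[1] = "\t".join(cells)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 2, column 4"):
            read_matrix(path)

    def test_ragged_row_raises(self, tmp_path, toy_coords):
        structures = [make_structure(f"s{i}", toy_coords) for i in range(2)]
        matrix = build_matrix(structures, structures[0].keys())
        path = tmp_path / "m.tsv"
        write_matrix(matrix, path)
        lines = path.read_text().splitlines()
        lines[2] = "\t".join(lines[2].split("\t")[:-1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 3"):
            read_matrix(path)
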