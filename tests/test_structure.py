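import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filterdca import structure
from filterdca.structure import (
    ContactMap,
    DistanceMatrix,
    ResidueCoords,
    SSAnnotation,
    classify_contact,
    contact_map,
    dataset_filters,
    merge_distance_matrices,
    min_heavy_atom_distances,
    ss_three_state,
)


class TestMinHeavyAtomDistances:
    def test_single_atom_pair(self):
        a = ResidueCoords([[(0.0, 0.0, 0.0)]])
        b = ResidueCoords([[(3.0, 0.0, 0.0)]])
        d = min_heavy_atom_distances(a, b)
        assert d.values[0, 0] == pytest.approx(3.0)

    def test_minimum_of_two_atoms(self):
        a = ResidueCoords([[(0.0, 0.0, 0.0)]])
        b = ResidueCoords([np.array([[9.0, 0.0, 0.0], [4.0, 0.0, 0.0]])])
        assert min_heavy_atom_distances(a, b).values[0, 0] == pytest.approx(4.0)

    def test_matches_brute_force(self, rng):
        coords_a = ResidueCoords([rng.normal(size=(rng.integers(1, 5), 3)) for _ in range(3)])
        coords_b = ResidueCoords([rng.normal(size=(rng.integers(1, 5), 3)) for _ in range(3)])
        d = min_heavy_atom_distances(coords_a, coords_b)
        for i, j in itertools.product(range(3), range(3)):
            best = min(
                float(np.linalg.norm(pa - pb))
                for pa in coords_a.atoms[i]
                for pb in coords_b.atoms[j]
            )
            assert d.values[i, j] == pytest.approx(best)

    def test_symmetric_under_domain_swap(self, rng):
        coords_a = ResidueCoords([rng.normal(size=(2, 3)) for _ in range(4)])
        coords_b = ResidueCoords([rng.normal(size=(2, 3)) for _ in range(5)])
        d_ab = min_heavy_atom_distances(coords_a, coords_b)
        d_ba = min_heavy_atom_distances(coords_b, coords_a)
        np.testing.assert_allclose(d_ab.values, d_ba.values.T)

    def test_zero_atom_residue_rejected(self):
        with pytest.raises(ValueError, match="residue 1"):
            ResidueCoords([[(0.0, 0.0, 0.0)], np.empty((0, 3))])


class TestMergeDistanceMatrices:
    def test_single_matrix_identity(self, rng):
        m = DistanceMatrix(rng.random((3, 4)))
        np.testing.assert_array_equal(merge_distance_matrices([m]).values, m.values)

    def test_pairwise_minimum(self):
        m1 = DistanceMatrix([[5.0]])
        m2 = DistanceMatrix([[9.0]])
        assert merge_distance_matrices([m1, m2]).values[0, 0] == 5.0

    def test_matches_loop_over_copies(self, rng):
        mats = [DistanceMatrix(rng.random((4, 5)) * 10) for _ in range(3)]
        merged = merge_distance_matrices(mats)
        for i in range(4):
            for j in range(5):
                assert merged.values[i, j] == min(m.values[i, j] for m in mats)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            merge_distance_matrices(
                [DistanceMatrix(rng.random((2, 2))), DistanceMatrix(rng.random((2, 3)))]
            )


class TestContactMap:
    def test_strict_inequality_at_threshold(self):
        d = DistanceMatrix([[7.99, 8.0]])
        cm = contact_map(d, 8.0)
        assert cm.values.tolist() == [[1, 0]]

    def test_matches_elementwise_comparison(self, rng):
        d = DistanceMatrix(rng.random((6, 7)) * 16)
        cm = contact_map(d, 8.0)
        np.testing.assert_array_equal(cm.values, (d.values < 8.0).astype(int))

    def test_min_then_threshold_equals_or_of_copies(self, rng):
        mats = [DistanceMatrix(rng.random((5, 5)) * 16) for _ in range(3)]
        merged_then_thresh = contact_map(merge_distance_matrices(mats), 8.0).values
        or_of_maps = np.zeros((5, 5), dtype=int)
        for m in mats:
            or_of_maps |= contact_map(m, 8.0).values.astype(int)
        np.testing.assert_array_equal(merged_then_thresh, or_of_maps)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            contact_map(DistanceMatrix([[1.0]]), 0.0)


class TestSSThreeState:
    def test_identity_on_h(self):
        assert ss_three_state("HHHH") == "HHHH"

    def test_mapping_definition(self):
        assert ss_three_state("GEB-T") == "HEEOO"

    def test_matches_lookup_table(self, rng):
        table = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}
        alphabet = list("HGIEBTSC-")
        s = "".join(rng.choice(alphabet) for _ in range(100))
        expected = "".join(table.get(c, "O") for c in s)
        assert ss_three_state(s) == expected

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError, match="position 2"):
            ss_three_state("HH?")


class TestClassifyContact:
    def test_hh(self):
        ss = SSAnnotation("HE")
        assert classify_contact(0, 0, ss, ss) == "HH"

    def test_mixed_is_other(self):
        assert classify_contact(0, 0, SSAnnotation("H"), SSAnnotation("E")) == "other"

    def test_exhaustive_table(self):
        for a, b in itertools.product("HEO", repeat=2):
            got = classify_contact(0, 0, SSAnnotation(a), SSAnnotation(b))
            if (a, b) == ("H", "H"):
                assert got == "HH"
            elif (a, b) == ("E", "E"):
                assert got == "EE"
            else:
                assert got == "other"

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            classify_contact(5, 0, SSAnnotation("H"), SSAnnotation("H"))


class TestDatasetFilters:
    @staticmethod
    def _map_with_contacts(n):
        values = np.zeros((50, 50), dtype=int)
        values.ravel()[:n] = 1
        return ContactMap(values)

    def test_too_few_contacts(self):
        ok, reasons = dataset_filters(self._map_with_contacts(9), 0.9)
        assert not ok and any("too few" in r for r in reasons)

    def test_bounds_inclusive(self):
        ok, reasons = dataset_filters(self._map_with_contacts(2000), 0.40)
        assert ok and reasons == []
        ok, _ = dataset_filters(self._map_with_contacts(10), 0.40)
        assert ok

    def test_coverage_boundary(self):
        ok, reasons = dataset_filters(self._map_with_contacts(100), 0.39)
        assert not ok and any("coverage" in r for r in reasons)


class TestIO:
    @staticmethod
    def _atom_line(serial, name, resname, chain, resseq, xyz, element, altloc=" "):
        x, y, z = xyz
        return (
            f"ATOM  {serial:>5} {name:<4}{altloc}{resname:>3} {chain}{resseq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n"
        )

    def test_pdb_reader_excludes_hydrogens_and_altlocs(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        lines = [
            self._atom_line(1, " CA", "ALA", "A", 1, (0, 0, 0), "C"),
            self._atom_line(2, " H", "ALA", "A", 1, (0.5, 0, 0), "H"),
            self._atom_line(3, " CA", "GLY", "A", 2, (3, 0, 0), "C", altloc="A"),
            self._atom_line(4, " CA", "GLY", "A", 2, (9, 9, 9), "C", altloc="B"),
            self._atom_line(5, " CA", "SER", "B", 1, (4, 0, 0), "C"),
        ]
        pdb.write_text("".join(lines) + "END\n")
        coords_a = structure.read_pdb_coords(pdb, "A")
        coords_b = structure.read_pdb_coords(pdb, "B")
        assert len(coords_a) == 2
        assert coords_a.atoms[0].shape == (1, 3)  # hydrogen dropped
        # altloc: first conformer kept
        np.testing.assert_allclose(coords_a.atoms[1][0], [3, 0, 0])
        d = min_heavy_atom_distances(coords_a, coords_b)
        assert d.values[0, 0] == pytest.approx(4.0)
        assert d.values[1, 0] == pytest.approx(1.0)

    def test_contact_map_roundtrip(self, tmp_path, rng):
        cm = ContactMap((rng.random((8, 11)) < 0.2).astype(int), threshold=8.0)
        path = tmp_path / "cm.tsv"
        structure.write_contact_map(cm, path)
        back = structure.read_contact_map(path)
        np.testing.assert_array_equal(back.values, cm.values)
        assert back.threshold == cm.threshold

    def test_distance_matrix_tsv(self, tmp_path):
        path = tmp_path / "dist.tsv"
        path.write_text("\t1\t2\t3\n1\t1.5\t9.0\t4.0\n2\t2.5\t8.0\t0.5\n")
        d = structure.read_distance_matrix_tsv(path)
        assert d.shape == (2, 3)
        assert d.values[1, 2] == 0.5

    def test_ss_file_roundtrip(self, tmp_path):
        path = tmp_path / "ss.txt"
        structure.write_ss_file(SSAnnotation("HHEEO"), SSAnnotation("OOEHH"), path)
        a, b = structure.read_ss_file(path)
        assert a.states == "HHEEO" and b.states == "OOEHH"


@given(st.text(alphabet="HGIEBTSC- ", min_size=1, max_size=80))
@settings(max_examples=50, deadline=None)
def test_three_state_output_alphabet(s):
    assert set(ss_three_state(s)) <= {"H", "E", "O"}
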