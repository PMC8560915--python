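"""Structure parsing, crosslink mapping, distance classification and
restraint-file round trips."""

import numpy as np
import pandas as pd
import pytest

from sedxl.simulate import InfeasibleConstraintError, ToyComplexSpec, gen_toy_complex
from sedxl.structure import (
    LinkRecord,
    StructureModel,
    link_distances,
    map_links,
    parse_restraints,
    read_structure,
    write_restraints,
)


@pytest.fixture
def straddle(tmp_path):
    """Toy complex with planted distances straddling the 30 A ceiling."""
    pairs = [("A", i + 1, "B", i + 1, d) for i, d in enumerate([5, 15, 25, 35, 45, 55])]
    spec = ToyComplexSpec(chain_lengths=(20, 20), planted_pairs=pairs, seed=2)
    path, truth = gen_toy_complex(spec, tmp_path / "toy.pdb")
    return path, truth, pairs


class TestToyGenerator:
    def test_planted_distances_realized_within_tolerance(self, straddle):
        path, truth, _ = straddle
        assert np.allclose(truth.requested_A, truth.realized_A, atol=0.01)

    def test_zero_pairs_valid_two_chain_file(self, tmp_path):
        path, truth = gen_toy_complex(
            ToyComplexSpec(chain_lengths=(8, 9), planted_pairs=[], seed=0),
            tmp_path / "empty.pdb",
        )
        assert len(truth) == 0
        model = read_structure(path)
        assert model.chain_length("A") == 8
        assert model.chain_length("B") == 9

    def test_deterministic_output(self, tmp_path):
        spec = ToyComplexSpec(chain_lengths=(10, 10),
                              planted_pairs=[("A", 2, "B", 3, 30.0)], seed=7)
        p1, _ = gen_toy_complex(spec, tmp_path / "a.pdb")
        p2, _ = gen_toy_complex(spec, tmp_path / "b.pdb")
        assert p1.read_bytes() == p2.read_bytes()

    def test_infeasible_constraints_name_the_pair(self, tmp_path):
        # same B residue pinned at two incompatible distances from one anchor
        spec = ToyComplexSpec(
            chain_lengths=(10, 10),
            planted_pairs=[("A", 1, "B", 1, 10.0), ("A", 1, "B", 1, 50.0)],
            seed=0,
        )
        with pytest.raises(InfeasibleConstraintError, match="B1"):
            gen_toy_complex(spec, tmp_path / "bad.pdb")

    def test_multiple_compatible_constraints_on_one_residue(self, tmp_path):
        spec = ToyComplexSpec(
            chain_lengths=(10, 10),
            planted_pairs=[("A", 1, "B", 5, 20.0), ("A", 9, "B", 5, 25.0)],
            seed=3,
        )
        _, truth = gen_toy_complex(spec, tmp_path / "two.pdb")
        assert np.allclose(truth.requested_A, truth.realized_A, atol=0.01)

    def test_out_of_range_residue_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ToyComplexSpec(chain_lengths=(5, 5), planted_pairs=[("A", 9, "B", 1, 10.0)])


class TestReadStructure:
    def test_round_trip_with_generator(self, straddle):
        path, truth, pairs = straddle
        model = read_structure(path)
        assert set(model.chains) == {"A", "B"}
        assert model.chain_length("A") == 20

    def test_minimal_two_residue_file_coordinates_exact(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA B   5       4.500  -2.250   0.125  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "mini.pdb"
        p.write_text(text)
        model = read_structure(p)
        np.testing.assert_array_equal(model.get_ca("A", 1), [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(model.get_ca("B", 5), [4.5, -2.25, 0.125])

    def test_no_calpha_rejected(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text(
            "ATOM      1  CB  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\nEND\n"
        )
        with pytest.raises(ValueError, match="Calpha"):
            read_structure(p)

    def test_missing_chain_flags_unresolved_not_raises(self, tmp_path):
        p = tmp_path / "onechain.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        )
        model = read_structure(p)
        report = link_distances(model, [("A", 1, "B", 1)])
        assert report.n_unresolved == 1
        assert report.n_satisfied == 0 and report.n_violated == 0


class TestMapLinks:
    def test_identity_mapping(self):
        links = [LinkRecord("DNJ-13", 44, "CDC-37", 60)]
        out = map_links(links, {"DNJ-13": "A", "CDC-37": "B"})
        assert out[0][:4] == ("A", 44, "B", 60)

    def test_offsets_shift_numbering(self):
        links = [LinkRecord("DNJ-13", 44, "CDC-37", 60)]
        out = map_links(links, {"DNJ-13": "A", "CDC-37": "B"},
                        {"CDC-37": -10})
        assert out[0][:4] == ("A", 44, "B", 50)

    def test_missing_chain_map_entry_raises(self):
        with pytest.raises(KeyError, match="CDC-37"):
            map_links([LinkRecord("DNJ-13", 44, "CDC-37", 60)], {"DNJ-13": "A"})

    def test_position_beyond_chain_flags_unresolved(self, straddle):
        path, _, _ = straddle
        model = read_structure(path)
        report = link_distances(model, [("A", 500, "B", 1)])
        assert report.table.unresolved.all()


class TestLinkDistances:
    def test_ceiling_boundary_is_inclusive(self):
        model = StructureModel(
            chains={"A": {1: np.zeros(3)}, "B": {1: np.array([0.0, 0.0, 30.0]),
                                                 2: np.array([0.0, 0.0, 30.0 + 1e-4])}}
        )
        rep = link_distances(model, [("A", 1, "B", 1), ("A", 1, "B", 2)], ceiling_A=30.0)
        assert rep.table.satisfied.tolist() == [True, False]

    def test_straddling_pairs_classified_3_3(self, straddle):
        path, _, pairs = straddle
        model = read_structure(path)
        rep = link_distances(model, [(a, ra, b, rb) for a, ra, b, rb, _ in pairs])
        assert rep.n_satisfied == 3
        assert rep.n_violated == 3
        # every satisfied link is within the ceiling
        ok = rep.table[rep.table.satisfied]
        assert (ok.measured_distance_A <= 30.0).all()

    def test_distance_symmetric_under_pair_swap(self, straddle):
        path, _, _ = straddle
        model = read_structure(path)
        d1 = link_distances(model, [("A", 3, "B", 4)]).table.measured_distance_A[0]
        d2 = link_distances(model, [("B", 4, "A", 3)]).table.measured_distance_A[0]
        assert d1 == d2 >= 0


class TestRestraints:
    def test_exact_line_dialect(self, tmp_path):
        p = write_restraints([("A", 50, "B", 35)], 30.0, tmp_path / "r.tbl")
        lines = p.read_text().splitlines()
        assert lines[1] == (
            "assign (segid A and resid 50 and name CA) "
            "(segid B and resid 35 and name CA) 30.0 30.0 0.0"
        )

    def test_round_trip_identity(self, tmp_path):
        pairs = [("A", 50, "B", 35), ("A", 44, "B", 60), ("B", 3, "A", 97)]
        p = write_restraints(pairs, 30.0, tmp_path / "r.tbl")
        assert parse_restraints(p) == pairs

    def test_duplicates_collapsed(self, tmp_path):
        pairs = [("A", 50, "B", 35), ("A", 50, "B", 35)]
        p = write_restraints(pairs, 30.0, tmp_path / "r.tbl")
        assert parse_restraints(p) == [("A", 50, "B", 35)]

    def test_empty_pairs_header_only(self, tmp_path):
        p = write_restraints([], 30.0, tmp_path / "r.tbl")
        assert parse_restraints(p) == []
        assert p.read_text().startswith("!")
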