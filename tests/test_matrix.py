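"""Distance-matrix assembly, neighbor rankings and the six relation checks."""

import numpy as np
import pytest

from mawdist import (
    AB,
    DistanceMatrix,
    SeqRecord,
    ValidationError,
    build_distance_matrix,
    evaluate_relations,
    ranked_neighbors,
    read_matrix_csv,
    write_matrix,
)
from mawdist.datasets import (
    BENCHMARK_SPECIES,
    jaccard_rc_reference_matrix,
    raw_lwi_rc_reference_matrix,
)

# Published neighbor orderings for the RAW length-weighted index (RC) matrix.
RAW_LWI_RANKINGS = {
    "Human": "Gorilla Chimp Rabbit Bovine Goat Mouse Opossum Lemur Rat Gallus",
    "Goat": "Bovine Gorilla Human Gallus Chimp Rabbit Mouse Lemur Rat Opossum",
    "Opossum": "Rabbit Gorilla Human Bovine Chimp Goat Mouse Gallus Rat Lemur",
    "Gallus": "Goat Bovine Rabbit Gorilla Human Lemur Opossum Mouse Chimp Rat",
    "Lemur": "Goat Bovine Rabbit Gorilla Human Gallus Mouse Chimp Rat Opossum",
    "Mouse": "Gorilla Bovine Chimp Human Rabbit Goat Rat Opossum Lemur Gallus",
    "Rabbit": "Gorilla Human Chimp Bovine Mouse Goat Gallus Opossum Lemur Rat",
    "Rat": "Mouse Goat Human Bovine Gorilla Rabbit Chimp Opossum Gallus Lemur",
    "Gorilla": "Human Chimp Rabbit Bovine Mouse Goat Opossum Lemur Gallus Rat",
    "Bovine": "Goat Gorilla Human Chimp Rabbit Mouse Lemur Gallus Rat Opossum",
    "Chimp": "Human Gorilla Rabbit Bovine Mouse Goat Opossum Rat Lemur Gallus",
}

# Published neighbor orderings for the Jaccard (RC) matrix; its 2-decimal
# values contain ties, so these rows are checked per tie block.
JACCARD_RANKINGS = {
    "Human": "Gorilla Chimp Rabbit Bovine Mouse Goat Lemur Gallus Rat Opossum",
    "Goat": "Bovine Gorilla Human Chimp Lemur Gallus Rabbit Mouse Rat Opossum",
    "Opossum": "Chimp Human Gorilla Rabbit Goat Gallus Bovine Lemur Rat Mouse",
    "Gallus": "Goat Rabbit Human Gorilla Chimp Bovine Lemur Mouse Opossum Rat",
    "Lemur": "Bovine Goat Gorilla Human Chimp Rabbit Rat Gallus Mouse Opossum",
    "Mouse": "Gorilla Chimp Human Bovine Goat Rat Rabbit Gallus Lemur Opossum",
    "Rabbit": "Human Gorilla Chimp Bovine Goat Mouse Gallus Lemur Rat Opossum",
    "Rat": "Mouse Goat Human Gorilla Rabbit Lemur Chimp Bovine Gallus Opossum",
    "Gorilla": "Human Chimp Rabbit Mouse Bovine Goat Lemur Gallus Rat Opossum",
    "Bovine": "Goat Gorilla Human Chimp Lemur Mouse Rabbit Gallus Rat Opossum",
    "Chimp": "Gorilla Human Rabbit Mouse Bovine Goat Lemur Gallus Opossum Rat",
}


class TestBuildMatrix:
    def test_identical_records_zero(self):
        recs = [SeqRecord("a", ("ACGTAC",)), SeqRecord("b", ("ACGTAC",))]
        m = build_distance_matrix(recs, "lwi_sym")
        assert np.allclose(m.values, 0.0)

    def test_jaccard_toy_pair(self, abbaab, aab):
        m = build_distance_matrix([abbaab, aab], "jaccard")
        assert m["x", "y"] == pytest.approx(6 / 7)

    @pytest.mark.parametrize("measure", ["lwi_sym", "jaccard", "raw_lwi", "gcc_sym"])
    @pytest.mark.parametrize("setting", ["noRC", "RC"])
    def test_symmetric_zero_diagonal_contract(self, rng, measure, setting):
        from mawdist.simulate import random_records

        m = build_distance_matrix(random_records(rng, 4, 30), measure, setting)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_rc_setting_changes_word_sets(self):
        # CC occurs only on the reverse strand of GG; RC setting sees it
        recs = [SeqRecord("a", ("GGGGGG",)), SeqRecord("b", ("CCCCCC",))]
        no_rc = build_distance_matrix(recs, "jaccard", "noRC")
        rc = build_distance_matrix(recs, "jaccard", "RC")
        assert no_rc["a", "b"] > 0.0
        assert rc["a", "b"] == 0.0  # identical up to strand

    def test_fewer_than_two_records(self):
        with pytest.raises(ValidationError, match="at least 2"):
            build_distance_matrix([SeqRecord("a", ("ACG",))], "jaccard")


class TestRankedNeighbors:
    def test_reference_raw_lwi_rows_exact(self):
        rankings = {r.focal: r.ordered for r in ranked_neighbors(raw_lwi_rc_reference_matrix())}
        for focal, expected in RAW_LWI_RANKINGS.items():
            assert rankings[focal] == tuple(expected.split()), focal

    def test_reference_jaccard_rows_up_to_ties(self):
        m = jaccard_rc_reference_matrix()
        rankings = {r.focal: r.ordered for r in ranked_neighbors(m)}
        for focal, expected in JACCARD_RANKINGS.items():
            got = rankings[focal]
            exp = tuple(expected.split())
            # same multiset within each run of equal distances
            got_d = [m[focal, lab] for lab in got]
            exp_d = [m[focal, lab] for lab in exp]
            assert got_d == sorted(got_d) and exp_d == sorted(exp_d), focal
            blocks_got: dict[float, set] = {}
            blocks_exp: dict[float, set] = {}
            for lab, d in zip(got, got_d):
                blocks_got.setdefault(d, set()).add(lab)
            for lab, d in zip(exp, exp_d):
                blocks_exp.setdefault(d, set()).add(lab)
            assert blocks_got == blocks_exp, focal

    def test_two_label_degenerate(self):
        m = DistanceMatrix(("A", "B"), [[0.0, 1.0], [1.0, 0.0]])
        assert [r.ordered for r in ranked_neighbors(m)] == [("B",), ("A",)]

    def test_lexicographic_tie_break(self):
        m = DistanceMatrix(
            ("C", "A", "B"), [[0, 1, 1], [1, 0, 2], [1, 2, 0]]
        )
        ranking = next(r for r in ranked_neighbors(m) if r.focal == "C")
        assert ranking.ordered[0] == "A"  # tie at distance 1 broken lexicographically


class TestRelations:
    def test_reference_raw_lwi_all_six(self):
        report = evaluate_relations(raw_lwi_rc_reference_matrix())
        assert all(report.satisfied.values())
        assert report.n_satisfied == 6

    def test_reference_jaccard_core_relations(self):
        report = evaluate_relations(jaccard_rc_reference_matrix())
        assert report.satisfied["REL1"]
        assert report.satisfied["REL2"]
        assert report.satisfied["REL3"]

    def test_constructed_counterexample(self):
        # Human glued to Rat: REL1 must fail
        m0 = raw_lwi_rc_reference_matrix()
        values = m0.values.copy()
        i, j = m0.labels.index("Human"), m0.labels.index("Rat")
        values[i, j] = values[j, i] = 0.01
        report = evaluate_relations(DistanceMatrix(m0.labels, values))
        assert not report.satisfied["REL1"]

    def test_missing_species_listed(self):
        m = DistanceMatrix(("A", "B"), [[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValidationError, match="Human"):
            evaluate_relations(m)

    def test_chimpanzee_alias_accepted(self):
        m0 = raw_lwi_rc_reference_matrix()
        labels = tuple("Chimpanzee" if l == "Chimp" else l.upper() for l in m0.labels)
        report = evaluate_relations(DistanceMatrix(labels, m0.values))
        assert report.n_satisfied == 6


class TestMatrixIO:
    def test_csv_round_trip(self, tmp_path):
        m = raw_lwi_rc_reference_matrix()
        path = tmp_path / "m.csv"
        write_matrix(m, "csv", path)
        back = read_matrix_csv(path)
        assert back.labels == m.labels
        assert np.abs(back.values - m.values).max() < 1e-12

    def test_phylip_shape(self, tmp_path):
        path = tmp_path / "m.phy"
        write_matrix(raw_lwi_rc_reference_matrix(), "phylip", path)
        lines = path.read_text().splitlines()
        assert lines[0] == "11"
        assert len(lines) == 12
        assert lines[1].split()[0] == "Human"

    def test_two_by_two_phylip(self, tmp_path):
        m = DistanceMatrix(("A", "B"), [[0.0, 0.0], [0.0, 0.0]])
        path = tmp_path / "z.phy"
        write_matrix(m, "phylip", path)
        lines = path.read_text().splitlines()
        assert lines[0] == "2" and len(lines) == 3
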