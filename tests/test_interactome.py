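"""Edge-list loading, thresholding, transition matrices and sequence matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drugwalk.interactome import (
    EdgeListError,
    ProteinRecord,
    build_graph,
    build_transition_matrix,
    dichotomize,
    load_edge_list,
    match_protein_records,
)
from .conftest import edge_list


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadEdgeList:
    def test_bidirectional_pair_collapses_to_one_edge(self, tmp_path):
        p = _write(tmp_path, "A\tB\t700\nB\tA\t700\nA\tC\t500\nC\tA\t500\n")
        el = load_edge_list(p)
        assert el.n_edges == 2
        row = el.edges[(el.edges.node_a == "A") & (el.edges.node_b == "B")]
        assert row["score"].item() == 700

    def test_self_edge_dropped(self, tmp_path):
        p = _write(tmp_path, "A\tA\t900\n")
        assert load_edge_list(p).n_edges == 0

    def test_duplicates_keep_max_score(self, tmp_path):
        # 10 rows, one pair listed twice with scores 400/600 -> 9 edges
        rows = [f"N{i}\tN{i+1}\t{500 + i}" for i in range(8)]
        rows += ["X\tY\t400", "Y\tX\t600"]
        el = load_edge_list(_write(tmp_path, "\n".join(rows) + "\n"))
        assert el.n_edges == 9
        assert el.edges.set_index(["node_a", "node_b"]).loc[("X", "Y"), "score"] == 600

    def test_header_autodetected(self, tmp_path):
        p = _write(tmp_path, "node1\tnode2\tcombined_score\nA\tB\t800\n")
        el = load_edge_list(p)
        assert el.n_edges == 1

    def test_score_column_by_name(self, tmp_path):
        p = _write(tmp_path, "node1\tnode2\tother\tcombined_score\nA\tB\t1\t800\n")
        el = load_edge_list(p, score_column="combined_score")
        assert el.edges["score"].item() == 800

    def test_malformed_row_names_line_number(self, tmp_path):
        p = _write(tmp_path, "A\tB\t700\nA\tB\n")
        with pytest.raises(EdgeListError, match="line 2"):
            load_edge_list(p)

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(EdgeListError, match="empty"):
            load_edge_list(_write(tmp_path, ""))

    def test_unit_scale_scores_rescaled(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.9\nB\tC\t0.5\n")
        el = load_edge_list(p)
        assert set(el.edges["score"]) == {round(0.9 * 999), round(0.5 * 999)}


class TestDichotomize:
    EDGES = [("A", "B", 300), ("B", "C", 400), ("C", "D", 600), ("D", "E", 850), ("E", "A", 900)]

    def test_threshold_zero_keeps_all(self):
        g = dichotomize(edge_list(self.EDGES), 0)
        assert g.n_edges == 5

    def test_threshold_600_keeps_three(self):
        g = dichotomize(edge_list(self.EDGES), 600)
        assert g.n_edges == 3

    @pytest.mark.parametrize("threshold", [400, 600, 700, 800, 850])
    def test_canonical_grid_accepted(self, threshold):
        dichotomize(edge_list(self.EDGES), threshold)

    def test_out_of_range_threshold_errors(self):
        with pytest.raises(ValueError):
            dichotomize(edge_list(self.EDGES), 1000)

    def test_dangling_nodes_retained(self):
        g = dichotomize(edge_list(self.EDGES), 999)
        assert g.n_edges == 0
        assert g.nodes == ["A", "B", "C", "D", "E"]

    def test_edge_count_monotone_in_threshold(self, small_dataset):
        counts = [
            dichotomize(small_dataset.edges, t).n_edges for t in range(0, 1000, 50)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_adjacency_symmetric(self, small_dataset):
        g = dichotomize(small_dataset.edges, 500)
        assert (g.adjacency != g.adjacency.T).nnz == 0

    def test_node_order_lexicographic(self):
        g = dichotomize(edge_list([("Z", "A", 500), ("M", "Z", 500)]), 0)
        assert g.nodes == sorted(g.nodes)


class TestTransitionMatrix:
    def test_path_graph_rows(self, path_graph):
        W = path_graph.transition.toarray()
        np.testing.assert_allclose(W[0], [0, 1, 0])
        np.testing.assert_allclose(W[1], [0.5, 0, 0.5])
        np.testing.assert_allclose(W[2], [0, 1, 0])

    def test_isolated_node_gets_self_loop(self):
        g = build_graph(edge_list([("A", "B", 900), ("C", "D", 100)]), 500)
        W = g.transition.toarray()
        i, j = g.index["C"], g.index["D"]
        assert W[i, i] == 1.0 and W[j, j] == 1.0

    def test_row_sums_on_random_graph(self, rng):
        n = 50
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < 0.1
        rows = [(f"N{a:02d}", f"N{b:02d}", 500) for a, b in zip(iu[keep], ju[keep])]
        g = build_graph(edge_list(rows), 0)
        sums = np.asarray(g.transition.sum(axis=1)).ravel()
        assert np.max(np.abs(sums - 1.0)) <= 1e-12

    @given(threshold=st.integers(min_value=0, max_value=999))
    @settings(max_examples=25, deadline=None)
    def test_row_stochastic_at_any_threshold(self, threshold):
        rows = [("A", "B", 300), ("B", "C", 600), ("C", "D", 900), ("A", "D", 450)]
        g = build_graph(edge_list(rows), threshold)
        sums = np.asarray(g.transition.sum(axis=1)).ravel()
        assert np.max(np.abs(sums - 1.0)) <= 1e-12


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestMatchProteinRecords:
    def test_exact_match(self, rng):
        seq = _random_seq(rng, 120)
        table = match_protein_records(
            [ProteinRecord("l1", sequence=seq)], [ProteinRecord("r1", sequence=seq)]
        )
        assert table.iloc[0]["tier"] == "exact"
        assert table.iloc[0]["right_id"] == "r1"

    def test_substring_match(self, rng):
        long_seq = _random_seq(rng, 200)
        table = match_protein_records(
            [ProteinRecord("l1", sequence=long_seq[40:120])],
            [ProteinRecord("r1", sequence=long_seq)],
        )
        assert table.iloc[0]["tier"] == "substring"

    @pytest.mark.parametrize("n_subs,expected", [(5, "fuzzy"), (6, "unmatched")])
    def test_five_percent_mismatch_boundary(self, rng, n_subs, expected):
        # 5/100 <= 0.05 < 6/100: five substitutions in a 100-aa sequence match
        seq = _random_seq(rng, 100)
        mutated = list(seq)
        pos = rng.choice(100, size=n_subs, replace=False)
        for p in pos:
            mutated[p] = "W" if seq[p] != "W" else "Y"
        table = match_protein_records(
            [ProteinRecord("l1", sequence="".join(mutated))],
            [ProteinRecord("r1", sequence=seq)],
            max_mismatch_frac=0.05,
        )
        assert table.iloc[0]["tier"] == expected
        if expected == "fuzzy":
            assert table.iloc[0]["mismatch_frac"] == pytest.approx(n_subs / 100)

    def test_duplicate_record_id_errors(self):
        recs = [ProteinRecord("x", sequence="MKV"), ProteinRecord("x", sequence="MKL")]
        with pytest.raises(ValueError, match="duplicate"):
            match_protein_records(recs, [ProteinRecord("r", sequence="MKV")])

    def test_tiers_disjoint_and_exhaustive(self, rng):
        base = [_random_seq(rng, 90) for _ in range(4)]
        left = [ProteinRecord(f"l{i}", sequence=s) for i, s in enumerate(base)]
        right = [
            ProteinRecord("r0", sequence=base[0]),                      # exact
            ProteinRecord("r1", sequence=base[1][10:70]),               # substring
            ProteinRecord("r2", sequence=base[2][:87] + "WWW"),         # fuzzy (3/90)
            # base[3] has no counterpart -> unmatched
        ]
        table = match_protein_records(left, right).set_index("left_id")
        assert table.loc["l0", "tier"] == "exact"
        assert table.loc["l1", "tier"] == "substring"
        assert table.loc["l2", "tier"] == "fuzzy"
        assert table.loc["l3", "tier"] == "unmatched"
        matched = table[table.tier != "unmatched"]["right_id"]
        assert matched.is_unique

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError, match="amino-acid"):
            ProteinRecord("x", sequence="MK1")
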