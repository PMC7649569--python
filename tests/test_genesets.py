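"""Gene-set construction, redundancy detection, overlap matrices, clustering."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from pathfig.genesets import (
    FigureGeneSet,
    build_sets,
    cluster_sets,
    filter_by_size,
    find_contained,
    find_duplicates,
    linkage_to_newick,
    overlap_matrix,
    read_gmt,
    write_gmt,
)


def _sets(*gene_lists, ids=None):
    ids = ids or [f"F{i}" for i in range(len(gene_lists))]
    return [FigureGeneSet(figure_id=i, genes=frozenset(g)) for i, g in zip(ids, gene_lists)]


def _random_sets(n, pool=30, max_size=8, seed=0):
    rng = random.Random(seed)
    out = []
    for i in range(n):
        size = rng.randint(1, max_size)
        out.append(FigureGeneSet(figure_id=f"F{i}", genes=frozenset(rng.sample(range(pool), size))))
    return out


def test_build_sets_deduplicates_instances():
    hits = pd.DataFrame(
        {
            "figure_id": ["F1", "F1", "F1"],
            "pmcid": ["PMC1"] * 3,
            "ncbi_gene_id": [7157, 7157, 207],
        }
    )
    sets = build_sets(hits)
    assert len(sets) == 1
    assert sets[0].genes == frozenset({7157, 207})
    assert sets[0].pmcid == "PMC1"


def test_build_sets_empty_table():
    assert build_sets(pd.DataFrame(columns=["figure_id", "ncbi_gene_id"])) == []


def test_build_sets_missing_metadata_warns(caplog):
    hits = pd.DataFrame({"figure_id": ["F1"], "ncbi_gene_id": [7157]})
    meta = pd.DataFrame({"figure_id": ["F2"], "pmcid": ["PMC2"], "year": [2001], "figure_title": ["t"]})
    with caplog.at_level("WARNING"):
        sets = build_sets(hits, meta)
    assert sets[0].pmcid is None
    assert any("no metadata" in r.message for r in caplog.records)


def test_filter_by_size_inclusive_threshold():
    sets = _sets(range(3), range(7), range(12))
    assert [len(s.genes) for s in filter_by_size(sets, 7)] == [7, 12]
    assert filter_by_size(sets, 1) == sets
    with pytest.raises(ValueError):
        filter_by_size(sets, 0)


class TestDuplicatesAndContainment:
    def test_duplicate_group(self):
        sets = _sets({1, 2}, {1, 2}, {1}, ids=["F1", "F2", "F3"])
        assert find_duplicates(sets) == [["F1", "F2"]]

    def test_all_distinct(self):
        assert find_duplicates(_sets({1}, {2}, {1, 2})) == []

    def test_strict_containment(self):
        sets = _sets({1}, {1, 2}, ids=["inner", "outer"])
        assert find_contained(sets) == [("inner", "outer")]

    def test_identical_sets_are_not_contained(self):
        sets = _sets({1, 2}, {1, 2})
        assert find_contained(sets) == []

    def test_against_brute_force_oracle(self):
        """Duplicates and containment match the O(n^2) set-comparison oracle."""
        sets = _random_sets(200, seed=3)
        # oracle: pairwise comparisons
        dup_pairs = set()
        cont_pairs = set()
        for a, b in itertools.permutations(sets, 2):
            if a.genes == b.genes and a.figure_id < b.figure_id:
                dup_pairs.add((a.figure_id, b.figure_id))
            if a.genes < b.genes:
                cont_pairs.add((a.figure_id, b.figure_id))
        got_groups = find_duplicates(sets)
        got_dup_pairs = {
            (x, y) for grp in got_groups for x, y in itertools.combinations(sorted(grp), 2)
        }
        assert got_dup_pairs == dup_pairs
        assert set(find_contained(sets)) == cont_pairs

    def test_duplicates_and_containment_disjoint(self):
        sets = _random_sets(100, seed=5)
        dups = {frozenset(g) for grp in find_duplicates(sets) for g in itertools.combinations(grp, 2)}
        cont = {frozenset(p) for p in find_contained(sets)}
        assert dups.isdisjoint(cont)


class TestOverlapMatrix:
    def test_worked_jaccard(self):
        m = overlap_matrix(_sets({"A", "B", "C"}, {"B", "C", "D"}))
        assert m.jaccard[0, 1] == pytest.approx(0.5)  # 2 shared / 4 union

    def test_directional_overlap(self):
        m = overlap_matrix(_sets({"A", "B"}, {"A", "B", "C", "D"}))
        assert m.overlap[0, 1] == pytest.approx(1.0)  # subset row scores 1
        assert m.overlap[1, 0] == pytest.approx(0.5)

    def test_disjoint_sets(self):
        m = overlap_matrix(_sets({1}, {2}))
        assert m.jaccard[0, 1] == 0.0
        assert m.overlap[0, 1] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_matrix(_sets({1}, set()))

    def test_against_naive_set_arithmetic(self):
        """Matrix entries equal direct set arithmetic on all pairs (n=60)."""
        sets = _random_sets(60, seed=11)
        m = overlap_matrix(sets)
        for i, a in enumerate(sets):
            for j, b in enumerate(sets):
                inter = len(a.genes & b.genes)
                assert m.jaccard[i, j] == pytest.approx(inter / len(a.genes | b.genes))
                assert m.overlap[i, j] == pytest.approx(inter / len(a.genes))

    def test_invariants(self):
        sets = _random_sets(40, seed=13)
        m = overlap_matrix(sets)
        assert np.allclose(np.diag(m.jaccard), 1.0)
        assert np.allclose(np.diag(m.overlap), 1.0)
        assert np.allclose(m.jaccard, m.jaccard.T)
        # jaccard never exceeds either directional overlap
        assert (m.jaccard <= np.minimum(m.overlap, m.overlap.T) + 1e-12).all()


class TestClustering:
    def test_identical_sets_merge_at_zero(self):
        sets = _sets({1, 2}, {1, 2}, {5, 6, 7})
        m = overlap_matrix(sets)
        Z, _ = cluster_sets(m)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_clear_pair_merges_first(self):
        # hand-computed: F0/F1 share 2 of 3 genes, F2 is disjoint
        sets = _sets({1, 2, 3}, {2, 3, 4}, {9, 10, 11})
        m = overlap_matrix(sets)
        Z, leaf_order = cluster_sets(m)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.5)  # 1 - jaccard(F0,F1)
        assert leaf_order.index("F2") in (0, 2)

    def test_cut_matches_connected_components_oracle(self):
        """Cluster count at a cut equals single-linkage connected components."""
        from scipy.cluster.hierarchy import fcluster
        import networkx as nx

        sets = _random_sets(50, seed=17)
        m = overlap_matrix(sets)
        Z, _ = cluster_sets(m, linkage="single")
        threshold = 0.6
        labels = fcluster(Z, t=threshold, criterion="distance")
        got = len(set(labels))
        g = nx.Graph()
        g.add_nodes_from(range(len(sets)))
        for i, j in itertools.combinations(range(len(sets)), 2):
            if 1.0 - m.jaccard[i, j] <= threshold:
                g.add_edge(i, j)
        assert got == nx.number_connected_components(g)

    def test_too_few_sets_rejected(self):
        m = overlap_matrix(_sets({1, 2}))
        with pytest.raises(ValueError):
            cluster_sets(m)

    def test_newick_is_parseable(self):
        import dendropy

        sets = _random_sets(10, seed=19)
        Z, _ = cluster_sets(overlap_matrix(sets))
        nwk = linkage_to_newick(Z, [s.figure_id for s in sets])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 10


def test_gmt_round_trip(tmp_path):
    sets = [
        FigureGeneSet("fig1", frozenset({7157, 207}), pmcid="PMC1", title="a figure"),
        FigureGeneSet("fig2", frozenset({9113})),
    ]
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    back = read_gmt(path)
    assert back["PMC1__fig1"] == ("a figure", frozenset({207, 7157}))
    assert back["fig2"] == ("", frozenset({9113}))


def test_gmt_malformed_line_names_lineno(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("ok\tdesc\t1\nbroken_line\n", encoding="utf-8")
    with pytest.raises(ValueError, match="line 2"):
        read_gmt(path)


def test_gmt_symbol_output(tmp_path):
    sets = [FigureGeneSet("f", frozenset({207}))]
    path = tmp_path / "sym.gmt"
    write_gmt(sets, path, use_symbols={207: "AKT1"})
    assert read_gmt(path)["f"][1] == frozenset({"AKT1"})
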