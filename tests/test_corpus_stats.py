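"""Corpus summaries, figure-vs-text comparison, classifier metrics, CIs, spans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathfig.corpus_stats import (
    classifier_metrics,
    compare_figure_vs_text,
    first_appearance_spans,
    novel_vs_databases,
    proportion_ci,
    summarize,
)
from pathfig.genesets import FigureGeneSet


def _set(fid, genes, year=None):
    return FigureGeneSet(figure_id=fid, genes=frozenset(genes), year=year)


class TestSummarize:
    def test_instance_mode_mean(self):
        hits = pd.DataFrame({"figure_id": ["F1"] * 3 + ["F2"] * 5,
                             "ncbi_gene_id": [1, 2, 2, 3, 4, 5, 6, 6]})
        sets = [_set("F1", {1, 2}), _set("F2", {3, 4, 5, 6})]
        s = summarize(sets, hits)
        assert s.total_instances == 8
        assert s.mean_genes_per_figure == pytest.approx(4.0)
        assert s.n_unique_genes == 6
        assert s.per_gene_figure_counts[2] == 1

    def test_unique_mode(self):
        hits = pd.DataFrame({"figure_id": ["F1"] * 3, "ncbi_gene_id": [1, 1, 2]})
        s = summarize([_set("F1", {1, 2})], hits, mode="unique")
        assert s.mean_genes_per_figure == pytest.approx(2.0)

    def test_empty_corpus_flags_undefined_mean(self):
        s = summarize([], pd.DataFrame(columns=["figure_id", "ncbi_gene_id"]))
        assert s.mean_genes_per_figure is None
        assert s.n_unique_genes == 0

    def test_total_includes_geneless_figures(self):
        hits = pd.DataFrame({"figure_id": ["F1"], "ncbi_gene_id": [1]})
        s = summarize([_set("F1", {1})], hits, n_figures_total=10)
        assert s.pct_figures_with_genes == pytest.approx(10.0)


class TestFigureVsText:
    def test_categories(self):
        fig = {"P1": {1, 2}, "P2": {3}}
        text = pd.DataFrame({"paper_id": ["P1", "P1", "P3"], "gene_id": [1, 9, 3]})
        frame = compare_figure_vs_text(fig, text).set_index("gene_id")
        assert frame.loc[1, "both"] == 1          # in figure and text of P1
        assert frame.loc[2, "figure_only"] == 1
        assert frame.loc[9, "text_only"] == 1
        assert frame.loc[3, "figure_only"] == 1   # P2 figure
        assert frame.loc[3, "text_only"] == 1     # P3 text

    def test_gene_absent_from_text_is_figure_only(self):
        frame = compare_figure_vs_text({"P1": {5}}, pd.DataFrame({"paper_id": [], "gene_id": []}))
        assert frame.set_index("gene_id").loc[5, "figure_only"] == 1

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(0)
        papers = [f"P{i}" for i in range(20)]
        fig = {p: set(rng.choice(50, size=rng.integers(1, 8), replace=False).tolist()) for p in papers[:15]}
        text_rows = [(p, int(g)) for p in papers[5:] for g in rng.choice(50, size=3, replace=False)]
        text = pd.DataFrame(text_rows, columns=["paper_id", "gene_id"])
        frame = compare_figure_vs_text(fig, text).set_index("gene_id")
        # oracle
        text_by_paper = {}
        for p, g in text_rows:
            text_by_paper.setdefault(p, set()).add(g)
        for g in frame.index:
            fo = sum(1 for p in papers if g in fig.get(p, set()) and g not in text_by_paper.get(p, set()))
            to = sum(1 for p in papers if g not in fig.get(p, set()) and g in text_by_paper.get(p, set()))
            bo = sum(1 for p in papers if g in fig.get(p, set()) and g in text_by_paper.get(p, set()))
            assert (frame.loc[g, "figure_only"], frame.loc[g, "text_only"], frame.loc[g, "both"]) == (fo, to, bo)


class TestNovelty:
    def test_all_covered(self):
        db = [{"s1": ("", frozenset({1, 2, 3}))}]
        covered, novel, genes = novel_vs_databases({1, 2}, db)
        assert (covered, novel, genes) == (2, 0, [])

    def test_empty_db_all_novel(self):
        covered, novel, genes = novel_vs_databases({1, 2}, [])
        assert (covered, novel, genes) == (0, 2, [1, 2])

    def test_partition(self):
        db = [{"a": ("", frozenset({1}))}, {"b": ("", frozenset({2, 5}))}]
        covered, novel, genes = novel_vs_databases({1, 2, 3}, db)
        assert covered + novel == 3
        assert genes == [3]


class TestClassifierMetrics:
    def test_perfect(self):
        m = classifier_metrics([1, 0, 1], [1, 0, 1])
        assert (m.precision, m.recall, m.mcc) == (1.0, 1.0, 1.0)

    def test_all_positive_on_balanced_gold(self):
        m = classifier_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert m.mcc is None  # degenerate column: undefined, not silently zero
        assert m.precision == pytest.approx(0.5)

    def test_derived_confusion_matrix(self):
        labels = [1] * 10 + [0] * 10
        preds = [1] * 9 + [0] + [1] + [0] * 9
        m = classifier_metrics(labels, preds)
        assert (m.tp, m.fp, m.fn, m.tn) == (9, 1, 1, 9)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.mcc == pytest.approx(0.8)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classifier_metrics([1], [1, 0])

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=60))
    def test_against_sklearn(self, pairs):
        """Hand-written MCC agrees with the independent sklearn computation."""
        from sklearn.metrics import matthews_corrcoef

        labels = [a for a, _ in pairs]
        preds = [b for _, b in pairs]
        m = classifier_metrics(labels, preds)
        if m.mcc is not None:
            assert m.mcc == pytest.approx(matthews_corrcoef(labels, preds), abs=1e-12)


class TestProportionCI:
    def test_reported_sample(self):
        # 94% pathway content judged on a 300-figure sample at 97% confidence
        half = proportion_ci(0.94, 300, 0.97)
        assert round(100 * half) == 3

    def test_closed_form_95(self):
        assert proportion_ci(0.5, 100, 0.95) == pytest.approx(0.098, abs=5e-4)

    def test_zero_variance_edges(self):
        assert proportion_ci(0.0, 50, 0.95) == 0.0
        assert proportion_ci(1.0, 50, 0.95) == 0.0

    def test_monotone_in_confidence_and_n(self):
        a = proportion_ci(0.3, 100, 0.90)
        b = proportion_ci(0.3, 100, 0.99)
        c = proportion_ci(0.3, 400, 0.90)
        assert b > a > c

    def test_wilson_available(self):
        w = proportion_ci(0.94, 300, 0.97, method="wilson")
        assert 0.0 < w < 0.1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            proportion_ci(1.5, 10, 0.95)
        with pytest.raises(ValueError):
            proportion_ci(0.5, 0, 0.95)
        with pytest.raises(ValueError):
            proportion_ci(0.5, 10, 1.0)


class TestFirstAppearanceSpans:
    def test_span_arithmetic(self):
        sets = [_set("F1", {10}, year=2007), _set("F2", {10, 20}, year=2010)]
        frame, median = first_appearance_spans(sets, {10: 1995, 20: 2000})
        row = frame.set_index("gene_id").loc[10]
        assert row["first_figure_year"] == 2007
        assert row["span_years"] == 12
        assert median == pytest.approx(11.0)  # spans 12 and 10

    def test_gene_without_event_year_excluded(self):
        sets = [_set("F1", {10, 30}, year=2007)]
        frame, _ = first_appearance_spans(sets, {10: 2000})
        assert list(frame["gene_id"]) == [10]

    def test_median_of_fixture_spans(self):
        sets = [_set(f"F{i}", {i}, year=2000 + s) for i, s in enumerate([1, 2, 3])]
        _, median = first_appearance_spans(sets, {0: 2000, 1: 2000, 2: 2000})
        assert median == pytest.approx(2.0)

    def test_negative_span_flagged(self):
        sets = [_set("F1", {10}, year=1998)]
        frame, _ = first_appearance_spans(sets, {10: 2005})
        assert bool(frame.iloc[0]["negative_span"]) is True
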