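"""Corpus-level summaries and comparisons.

Counts of recognized gene instances and unique genes, per-figure averages,
figure-vs-text comparison against a text-mining gene-paper table, novelty
against pathway-database collections, binary-classifier quality metrics
(precision, recall, Matthews correlation), Wald/Wilson binomial proportion
intervals, and gene first-appearance chronology (cloning-to-pathway spans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .genesets import FigureGeneSet

__all__ = [
    "CorpusSummary",
    "ClassifierMetrics",
    "summarize",
    "compare_figure_vs_text",
    "novel_vs_databases",
    "classifier_metrics",
    "proportion_ci",
    "first_appearance_spans",
]


@dataclass(frozen=True)
class CorpusSummary:
    n_figures_total: int
    n_figures_with_genes: int
    total_instances: int
    n_unique_genes: int
    mean_genes_per_figure: float | None  # None when no gene-containing figure
    per_gene_figure_counts: dict

    @property
    def pct_figures_with_genes(self) -> float | None:
        if self.n_figures_total == 0:
            return None
        return 100.0 * self.n_figures_with_genes / self.n_figures_total


@dataclass(frozen=True)
class ClassifierMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None
    recall: float | None
    mcc: float | None


def summarize(
    sets: Sequence[FigureGeneSet],
    hit_table: pd.DataFrame,
    n_figures_total: int | None = None,
    mode: str = "instances",
) -> CorpusSummary:
    """Tally the corpus.

    ``mode='instances'`` (default) averages recognized gene instances over
    gene-containing figures — total instances / figures with >= 1 gene;
    ``mode='unique'`` averages the per-figure unique-gene count instead.
    ``n_figures_total`` may exceed the number of sets when figures without
    hits are known to exist.
    """
    n_with = len(sets)
    total_instances = int(len(hit_table))
    unique_genes = set()
    per_gene: dict[int, int] = {}
    for s in sets:
        unique_genes |= s.genes
        for g in s.genes:
            per_gene[g] = per_gene.get(g, 0) + 1
    n_total = n_figures_total if n_figures_total is not None else n_with
    if n_total < n_with:
        raise ValueError("n_figures_total cannot be below the number of gene-containing figures")
    if n_with == 0:
        mean = None
    elif mode == "instances":
        mean = total_instances / n_with
    elif mode == "unique":
        mean = sum(len(s.genes) for s in sets) / n_with
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CorpusSummary(
        n_figures_total=n_total,
        n_figures_with_genes=n_with,
        total_instances=total_instances,
        n_unique_genes=len(unique_genes),
        mean_genes_per_figure=mean,
        per_gene_figure_counts=dict(sorted(per_gene.items())),
    )


def compare_figure_vs_text(
    figure_sets_by_paper: Mapping[str, Iterable],
    text_gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene paper counts in three categories: figure-only, text-only, both.

    ``figure_sets_by_paper`` maps paper id -> genes found in that paper's
    figures; ``text_gene_table`` has columns (paper_id, gene_id) from a
    text-mining source. Returns one row per gene with columns
    figure_only / text_only / both (paper counts).
    """
    if not {"paper_id", "gene_id"} <= set(text_gene_table.columns):
        raise ValueError("text gene table needs columns paper_id, gene_id")
    text_by_paper: dict[str, set[int]] = {}
    for _, row in text_gene_table.iterrows():
        text_by_paper.setdefault(str(row["paper_id"]), set()).add(int(row["gene_id"]))

    counts: dict[int, dict[str, int]] = {}
    papers = set(figure_sets_by_paper) | set(text_by_paper)
    for paper in papers:
        fig = {int(g) for g in figure_sets_by_paper.get(paper, ())}
        txt = text_by_paper.get(paper, set())
        for g in fig | txt:
            cat = "both" if (g in fig and g in txt) else ("figure_only" if g in fig else "text_only")
            row = counts.setdefault(g, {"figure_only": 0, "text_only": 0, "both": 0})
            row[cat] += 1
    frame = pd.DataFrame(
        [
            {"gene_id": g, **row}
            for g, row in sorted(counts.items())
        ]
    )
    return frame


def novel_vs_databases(
    unique_genes: Iterable,
    db_collections: Sequence[Mapping[str, tuple[str, frozenset]]],
) -> tuple[int, int, list]:
    """Split recognized genes into database-covered and database-novel.

    ``db_collections`` are parsed GMT mappings (name -> (description,
    members)); a gene is novel when no collection contains it.
    """
    genes = {int(g) for g in unique_genes}
    covered_pool: set[int] = set()
    for coll in db_collections:
        for _, members in coll.values():
            covered_pool |= {int(m) for m in members if isinstance(m, int) or str(m).isdigit()}
    covered = genes & covered_pool
    novel = sorted(genes - covered_pool)
    return len(covered), len(novel), novel


def classifier_metrics(labels: Sequence[int], predictions: Sequence[int]) -> ClassifierMetrics:
    """Precision, recall and Matthews correlation from binary gold/predicted labels.

    MCC = (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)). Undefined
    quantities (zero denominators) are returned as None rather than silently
    coerced to zero.
    """
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    lab = np.asarray(labels, dtype=int)
    pred = np.asarray(predictions, dtype=int)
    if not set(np.unique(np.concatenate([lab, pred]))) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((lab == 1) & (pred == 1)))
    fp = int(np.sum((lab == 0) & (pred == 1)))
    tn = int(np.sum((lab == 0) & (pred == 0)))
    fn = int(np.sum((lab == 1) & (pred == 0)))
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else None
    return ClassifierMetrics(tp=tp, fp=fp, tn=tn, fn=fn, precision=precision, recall=recall, mcc=mcc)


def proportion_ci(p_hat: float, n: int, confidence: float = 0.95, method: str = "wald") -> float:
    """Half-width of a binomial proportion confidence interval.

    Default is the Wald normal approximation z·sqrt(p(1−p)/n); ``wilson``
    switches to the Wilson score interval (its half-width is the half-range
    of the interval), better behaved at small n or extreme p.
    """
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    if method == "wald":
        z = norm.ppf((1.0 + confidence) / 2.0)
        return float(z * math.sqrt(p_hat * (1.0 - p_hat) / n))
    if method == "wilson":
        count = int(round(p_hat * n))
        lo, hi = proportion_confint(count, n, alpha=1.0 - confidence, method="wilson")
        return float((hi - lo) / 2.0)
    raise ValueError(f"unknown CI method {method!r}")


def first_appearance_spans(
    sets: Sequence[FigureGeneSet],
    event_table: Mapping[int, int],
) -> tuple[pd.DataFrame, float | None]:
    """Per-gene span between an event year (e.g. cloning) and first figure year.

    Genes never appearing in a year-annotated figure, or absent from the
    event table, are excluded. Negative spans (figure precedes the recorded
    event) are retained and flagged. Returns (table, median span).
    """
    first_year: dict[int, int] = {}
    for s in sets:
        if s.year is None:
            continue
        for g in s.genes:
            if g not in first_year or s.year < first_year[g]:
                first_year[g] = s.year
    rows = []
    for gene, year in sorted(first_year.items()):
        event = event_table.get(gene)
        if event is None:
            continue
        span = year - int(event)
        rows.append(
            {
                "gene_id": gene,
                "event_year": int(event),
                "first_figure_year": year,
                "span_years": span,
                "negative_span": span < 0,
            }
        )
    frame = pd.DataFrame(rows)
    median = float(frame["span_years"].median()) if len(frame) else None
    return frame, median
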