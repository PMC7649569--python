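"""Overrepresentation annotation of figure gene sets.

Each figure's gene set is tested against every term of an annotation
collection (disease terms, GO Biological Process, ...) with the one-sided
hypergeometric upper tail — the probability of drawing at least the observed
overlap ``k`` when ``n`` query genes are sampled without replacement from a
universe of ``N`` genes containing ``K`` term genes. P values are
Benjamini–Hochberg adjusted within each set across terms.

Collections can be read from GMT or from a 3-column TSV (term_id,
term_label, gene_id) as disease-gene association channels ship. Terms with
fewer associated genes than a cutoff (default 7) are removed first: tiny
terms make overrepresentation calls unstable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import FigureGeneSet, read_gmt

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "read_collection_gmt",
    "read_collection_tsv",
    "filter_collection",
    "hypergeometric_test",
    "annotate_sets",
    "dedup_top_terms",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationCollection:
    """Named terms, each a set of gene IDs, over a gene universe."""

    name: str
    terms: dict  # term_id -> (term_label, frozenset of gene ids)
    universe: frozenset

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {tid} has genes outside the universe")

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    """One (gene set, term) overrepresentation test."""

    set_id: str
    term_id: str
    term_label: str
    k: int  # overlap
    K: int  # term size
    n: int  # query size (within universe)
    N: int  # universe size
    p_value: float
    fdr: float


def _collection_from_terms(name, term_map, universe=None) -> AnnotationCollection:
    auto_universe = frozenset().union(*(g for _, g in term_map.values())) if term_map else frozenset()
    uni = frozenset(universe) if universe is not None else auto_universe
    # clip terms to the universe so invariants hold under a user universe
    clipped = {tid: (lbl, frozenset(g) & uni) for tid, (lbl, g) in term_map.items()}
    return AnnotationCollection(name=name, terms=clipped, universe=uni)


def read_collection_gmt(path, name: str = "collection", universe=None) -> AnnotationCollection:
    """Load a collection from GMT; term label is the GMT description."""
    raw = read_gmt(path)
    term_map = {tid: (desc or tid, frozenset(genes)) for tid, (desc, genes) in raw.items()}
    return _collection_from_terms(name, term_map, universe)


def read_collection_tsv(path, name: str = "collection", universe=None) -> AnnotationCollection:
    """Load a 3-column TSV (term_id, term_label, gene_id), one association per row."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(table.columns)
    if len(cols) < 3:
        raise ValueError("association TSV needs 3 columns: term_id, term_label, gene_id")
    tid_c, lbl_c, gid_c = cols[:3]
    term_map: dict[str, tuple[str, set]] = {}
    for _, row in table.iterrows():
        tid = row[tid_c]
        lbl = row[lbl_c]
        gid = int(row[gid_c])
        if tid not in term_map:
            term_map[tid] = (lbl, set())
        term_map[tid][1].add(gid)
    frozen = {tid: (lbl, frozenset(g)) for tid, (lbl, g) in term_map.items()}
    return _collection_from_terms(name, frozen, universe)


def filter_collection(raw: AnnotationCollection, min_genes: int = 7) -> AnnotationCollection:
    """Drop terms with fewer than ``min_genes`` genes; universe unchanged."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    kept = {tid: (lbl, genes) for tid, (lbl, genes) in raw.terms.items() if len(genes) >= min_genes}
    return AnnotationCollection(name=raw.name, terms=kept, universe=raw.universe)


def hypergeometric_test(query: Iterable, term: Iterable, universe: Iterable) -> float:
    """Upper-tail P(X >= k) for the overlap of query and term in the universe.

    X ~ Hypergeometric(N, K, n) with N the universe size, K the term size
    and n the query size; the observed overlap k is included in the tail.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query) & uni
    t = frozenset(term) & uni
    N, K, n = len(uni), len(t), len(q)
    k = len(q & t)
    return float(hypergeom.sf(k - 1, N, K, n))


def annotate_sets(
    sets: Sequence[FigureGeneSet],
    coll: AnnotationCollection,
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], dict[str, EnrichmentResult]]:
    """Test every set against every term; keep BH-significant results.

    Returns the significant results (FDR < alpha, BH within each set across
    terms) and each set's top term — smallest FDR, ties broken by larger
    overlap then lexicographic term id.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    N = len(coll.universe)
    significant: list[EnrichmentResult] = []
    top_terms: dict[str, EnrichmentResult] = {}
    term_items = sorted(coll.terms.items())
    for s in sets:
        q = frozenset(s.genes) & coll.universe
        n = len(q)
        raw: list[EnrichmentResult] = []
        for tid, (lbl, genes) in term_items:
            k = len(q & genes)
            p = float(hypergeom.sf(k - 1, N, len(genes), n))
            raw.append(EnrichmentResult(s.figure_id, tid, lbl, k, len(genes), n, N, p, 1.0))
        if not raw:
            continue
        _, fdrs, _, _ = multipletests([r.p_value for r in raw], method="fdr_bh")
        adjusted = [
            EnrichmentResult(r.set_id, r.term_id, r.term_label, r.k, r.K, r.n, r.N, r.p_value, float(f))
            for r, f in zip(raw, fdrs)
        ]
        sig = [r for r in adjusted if r.fdr < alpha]
        significant.extend(sig)
        if sig:
            top = min(sig, key=lambda r: (r.fdr, -r.k, r.term_id))
            top_terms[s.figure_id] = top
    return significant, top_terms


def _merge_plural_labels(labels: Iterable[str]) -> dict[str, str]:
    """Map each label to its merged form: drop a trailing 'S' when both the
    singular and plural spellings occur (Tumor/Tumors -> Tumor)."""
    pool = set(labels)
    mapping = {}
    for lbl in pool:
        if lbl.upper().endswith("S") and lbl[:-1] in pool:
            mapping[lbl] = lbl[:-1]
        else:
            mapping[lbl] = lbl
    return mapping


def dedup_top_terms(
    item_terms: Mapping[str, Sequence[str]],
    top_n: int = 10,
) -> list[tuple[str, int]]:
    """Greedy non-redundant top-term ranking with exclusive item counts.

    ``item_terms`` maps each item (figure or paper) to the term labels it is
    associated with. Singular/plural label pairs are merged first. Then the
    term covering the most not-yet-counted items is picked, those items are
    assigned to it exclusively and removed, and the count is repeated up to
    ``top_n`` picks; remaining items are reported as ``("Other", count)``.
    Ties break lexicographically for determinism.
    """
    merge = _merge_plural_labels({t for terms in item_terms.values() for t in terms})
    remaining: dict[str, set[str]] = {
        item: {merge[t] for t in terms} for item, terms in item_terms.items() if terms
    }
    ranking: list[tuple[str, int]] = []
    for _ in range(top_n):
        if not remaining:
            break
        counts: dict[str, int] = {}
        for terms in remaining.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        if not counts:
            break
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        term, cnt = best
        ranking.append((term, cnt))
        remaining = {item: terms for item, terms in remaining.items() if term not in terms}
    other = len(remaining)
    if other:
        ranking.append(("Other", other))
    return ranking


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per set-term test kept)."""
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "term_id": r.term_id,
                "term_label": r.term_label,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
            }
            for r in results
        ]
    )
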