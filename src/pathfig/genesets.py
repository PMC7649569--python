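"""Per-figure gene sets and their redundancy structure.

Figures are reduced to sets of unique NCBI Gene IDs, size-filtered for
downstream enrichment use (small sets make overrepresentation statistics
unstable), and compared pairwise: exact duplicates, strict containments,
directional overlap (|A∩B|/|A|) and the Jaccard index (|A∩B|/|A∪B|).
Agglomerative clustering on 1−similarity orders figures into the nested
core/plus/meta structure pathway collections exhibit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "FigureGeneSet",
    "OverlapMatrix",
    "build_sets",
    "filter_by_size",
    "find_duplicates",
    "find_contained",
    "overlap_matrix",
    "cluster_sets",
    "write_gmt",
    "read_gmt",
    "linkage_to_newick",
    "plot_overlap_heatmap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FigureGeneSet:
    """One figure's unique gene content plus metadata."""

    figure_id: str
    genes: frozenset[int]
    pmcid: str | None = None
    year: int | None = None
    title: str | None = None


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise similarity between figure gene sets.

    ``overlap[i, j] = |genes_i ∩ genes_j| / |genes_i|`` (row-directional, so
    a subset scores 1 against its superset on the subset's row); ``jaccard``
    is symmetric with unit diagonal.
    """

    ids: tuple[str, ...]
    jaccard: np.ndarray
    overlap: np.ndarray

    def to_frame(self, which: str = "jaccard") -> pd.DataFrame:
        m = self.jaccard if which == "jaccard" else self.overlap
        return pd.DataFrame(m, index=list(self.ids), columns=list(self.ids))


def build_sets(hits: pd.DataFrame, metadata: pd.DataFrame | None = None) -> list[FigureGeneSet]:
    """Collapse a hit table to one gene set per figure (instances dedup to IDs).

    ``metadata`` is joined by figure_id (columns: figure_id + optional pmcid,
    year, figure_title); figures missing from it get null metadata with a
    warning.
    """
    meta_by_id: dict[str, dict] = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            meta_by_id[str(row["figure_id"])] = row.to_dict()

    sets: list[FigureGeneSet] = []
    if hits.empty:
        return sets
    for figure_id, grp in hits.groupby("figure_id", sort=True):
        genes = frozenset(int(g) for g in grp["ncbi_gene_id"].unique())
        meta = meta_by_id.get(str(figure_id))
        if metadata is not None and meta is None:
            logger.warning("figure %s has no metadata row", figure_id)
        pmcid = None
        year = None
        title = None
        if meta is not None:
            pmcid = str(meta["pmcid"]) if meta.get("pmcid") not in (None, "") else None
            year = int(meta["year"]) if meta.get("year") not in (None, "") else None
            title = str(meta["figure_title"]) if meta.get("figure_title") not in (None, "") else None
        elif "pmcid" in grp.columns:
            vals = [v for v in grp["pmcid"].unique() if v]
            pmcid = str(vals[0]) if vals else None
        sets.append(FigureGeneSet(figure_id=str(figure_id), genes=genes, pmcid=pmcid, year=year, title=title))
    return sets


def filter_by_size(sets: Sequence[FigureGeneSet], min_genes: int) -> list[FigureGeneSet]:
    """Keep sets with at least ``min_genes`` unique genes (inclusive), order kept."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    return [s for s in sets if len(s.genes) >= min_genes]


def find_duplicates(sets: Sequence[FigureGeneSet]) -> list[list[str]]:
    """Groups (size >= 2) of figures sharing the exact same gene content."""
    by_content: dict[frozenset[int], list[str]] = {}
    for s in sets:
        by_content.setdefault(s.genes, []).append(s.figure_id)
    groups = [sorted(ids) for ids in by_content.values() if len(ids) >= 2]
    return sorted(groups)


def find_contained(sets: Sequence[FigureGeneSet]) -> list[tuple[str, str]]:
    """Strict-containment pairs (inner, outer) with genes_inner ⊊ genes_outer.

    Exact duplicates are deliberately NOT containment: duplicate and
    contained figures are disjoint categories.
    """
    pairs = []
    for i, a in enumerate(sets):
        for b in sets:
            if a.figure_id != b.figure_id and a.genes < b.genes:
                pairs.append((a.figure_id, b.figure_id))
    return sorted(pairs)


def overlap_matrix(sets: Sequence[FigureGeneSet]) -> OverlapMatrix:
    """Compute Jaccard and directional-overlap matrices over all set pairs."""
    for s in sets:
        if not s.genes:
            raise ValueError(f"figure {s.figure_id} has an empty gene set")
    ids = tuple(s.figure_id for s in sets)
    n = len(sets)
    # incidence matrix over the union of genes: intersections via one matmul
    all_genes = sorted(set().union(*(s.genes for s in sets))) if sets else []
    gene_index = {g: k for k, g in enumerate(all_genes)}
    inc = np.zeros((n, len(all_genes)), dtype=np.float64)
    for i, s in enumerate(sets):
        for g in s.genes:
            inc[i, gene_index[g]] = 1.0
    inter = inc @ inc.T
    sizes = inc.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
        ovl = inter / sizes[:, None]
    np.fill_diagonal(jac, 1.0)
    np.fill_diagonal(ovl, 1.0)
    return OverlapMatrix(ids=ids, jaccard=jac, overlap=ovl)


def cluster_sets(
    m: OverlapMatrix,
    linkage: str = "average",
    distance: str = "jaccard_distance",
):
    """Hierarchical clustering of figures on 1 − similarity.

    ``distance`` chooses the similarity: ``jaccard_distance`` (default,
    symmetric) or ``overlap_distance`` (directional overlap symmetrized by
    the max so that nesting reads as closeness). Returns the scipy linkage
    matrix and the dendrogram leaf order (figure ids).
    """
    if len(m.ids) < 2:
        raise ValueError("clustering needs at least 2 sets")
    if distance == "jaccard_distance":
        sim = m.jaccard
    elif distance == "overlap_distance":
        sim = np.maximum(m.overlap, m.overlap.T)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [m.ids[i] for i in leaves]
    return Z, leaf_order


def linkage_to_newick(Z: np.ndarray, ids: Sequence[str]) -> str:
    """Render a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def _walk(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left = _walk(node.left)
        right = _walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return _walk(tree) + ";"


def write_gmt(sets: Sequence[FigureGeneSet], path, use_symbols: dict[int, str] | None = None) -> None:
    """Write sets in GMT format (name, description, members...).

    Set names are ``<pmcid>__<figure_id>`` (or the bare figure id without a
    PMCID) and the description is the figure title; members are NCBI Gene
    integers unless ``use_symbols`` maps them to symbols.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            name = f"{s.pmcid}__{s.figure_id}" if s.pmcid else s.figure_id
            desc = s.title or ""
            genes = sorted(s.genes)
            if use_symbols is not None:
                members = [use_symbols.get(g, str(g)) for g in genes]
            else:
                members = [str(g) for g in genes]
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """Read GMT into {name: (description, members)}; integer members coerced."""
    out: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = parts
            coerced = []
            for mbr in members:
                if not mbr:
                    continue
                try:
                    coerced.append(int(mbr))
                except ValueError:
                    coerced.append(mbr)
            out[name] = (desc, frozenset(coerced))
    return out


def plot_overlap_heatmap(m: OverlapMatrix, Z=None, which: str = "overlap", ax=None):
    """Heatmap of the (dendrogram-ordered) similarity matrix.

    Convenience rendering of the redundancy structure: rows/columns follow
    the clustering leaf order when a linkage is given.
    """
    import matplotlib.pyplot as plt

    sim = m.overlap if which == "overlap" else m.jaccard
    order = np.arange(len(m.ids))
    if Z is not None:
        order = hierarchy.leaves_list(Z)
    sim = sim[np.ix_(order, order)]
    labels = [m.ids[i] for i in order]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, len(labels) * 0.25),) * 2)
    im = ax.imshow(sim, cmap="viridis", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(labels)))
    ax.set_yticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_yticklabels(labels, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label=which)
    return ax
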