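"""Core recognition loop: transform rounds alternating with lexicon lookups.

For each OCR word the candidate rounds are walked in order (normalized word,
then OCR-error substitutions, decoration strips, multi-gene expansions). The
FIRST round producing at least one lexicon match wins and later rounds are
never consulted — a word that is itself a valid symbol must not also spawn
speculative edits of itself. Within a matched candidate only the best lexicon
tier is kept; a candidate whose best tier still maps to more than one gene
(an ambiguous alias) yields no hit and is logged for audit.

Hits are per word occurrence: the same symbol appearing twice in one figure
contributes two instances. Downstream set construction deduplicates by NCBI
Gene ID.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .figure_ocr import OcrDocument
from .lexicon import Lexicon
from .transforms import TransformChain, candidate_rounds, default_chain

__all__ = [
    "GeneHit",
    "RecognitionResult",
    "recognize_word",
    "recognize_document",
    "recognize_corpus",
    "hits_to_json_records",
    "write_hits_json",
    "HIT_COLUMNS",
]

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "figure_id",
    "pmcid",
    "word_index",
    "raw_word",
    "matched_variant",
    "official_symbol",
    "ncbi_gene_id",
    "lexicon_source",
]


@dataclass(frozen=True)
class GeneHit:
    """One recognized gene occurrence in one figure."""

    figure_id: str
    raw_word: str
    matched_variant: str
    official_symbol: str
    gene_id: int
    source: str
    word_index: int
    pmcid: str | None = None


@dataclass
class RecognitionResult:
    """Hits plus the audit trail for one document (or a merged corpus)."""

    hits: list[GeneHit] = field(default_factory=list)
    unmatched_words: list[tuple[str, str]] = field(default_factory=list)
    words_seen: int = 0
    words_matched: int = 0

    @property
    def hits_emitted(self) -> int:
        return len(self.hits)


def recognize_word(
    word: str,
    chain: TransformChain | None = None,
    lex: Lexicon | None = None,
) -> list[tuple[str, str, int, str]]:
    """Resolve one raw OCR word against the lexicon.

    Returns ``(matched_variant, official_symbol, gene_id, source)`` tuples,
    one per distinct gene, or ``[]`` when no round matches. ``lex`` is
    required; ``chain`` defaults to the shipped chain.
    """
    if lex is None:
        raise ValueError("a built Lexicon is required")
    ch = chain if chain is not None else default_chain()

    for round_candidates in candidate_rounds(word, ch):
        matched: list[tuple[str, str, int, str]] = []
        seen_genes: set[int] = set()
        any_match = False
        for cand in round_candidates:
            entries = lex.lookup(cand)
            if not entries:
                continue
            any_match = True
            best_tier = entries[0].source
            best = [e for e in entries if e.source == best_tier]
            distinct_genes = {e.gene_id for e in best}
            if len(distinct_genes) > 1:
                logger.info(
                    "ambiguous alias %r -> %d genes at tier %s; dropped",
                    cand,
                    len(distinct_genes),
                    best_tier,
                )
                continue
            entry = best[0]
            if entry.gene_id not in seen_genes:
                seen_genes.add(entry.gene_id)
                matched.append((cand, entry.official_symbol, entry.gene_id, entry.source))
        if any_match:
            return matched
    return []


def recognize_document(
    doc: OcrDocument,
    chain: TransformChain | None = None,
    lex: Lexicon | None = None,
) -> RecognitionResult:
    """Recognize every word of one document; counters satisfy
    words_matched + |unmatched| == words_seen."""
    result = RecognitionResult()
    for idx, raw in enumerate(doc.words):
        result.words_seen += 1
        found = recognize_word(raw, chain, lex)
        if found:
            result.words_matched += 1
            for variant, symbol, gene_id, source in found:
                result.hits.append(
                    GeneHit(
                        figure_id=doc.figure_id,
                        raw_word=raw,
                        matched_variant=variant,
                        official_symbol=symbol,
                        gene_id=gene_id,
                        source=source,
                        word_index=idx,
                        pmcid=doc.pmcid,
                    )
                )
        else:
            result.unmatched_words.append((doc.figure_id, raw))
    return result


def recognize_corpus(
    docs: Iterable[OcrDocument],
    chain: TransformChain | None = None,
    lex: Lexicon | None = None,
    progress_every: int = 1000,
) -> pd.DataFrame:
    """Recognize a whole corpus into a deterministic hit table.

    Rows are sorted by (figure_id, word_index, ncbi_gene_id); duplicate
    figure ids are an input error.
    """
    rows = []
    seen_ids: set[str] = set()
    for n, doc in enumerate(docs, start=1):
        if doc.figure_id in seen_ids:
            raise ValueError(f"duplicate figure_id {doc.figure_id!r} in corpus")
        seen_ids.add(doc.figure_id)
        res = recognize_document(doc, chain, lex)
        for h in res.hits:
            rows.append(
                (
                    h.figure_id,
                    h.pmcid or "",
                    h.word_index,
                    h.raw_word,
                    h.matched_variant,
                    h.official_symbol,
                    h.gene_id,
                    h.source,
                )
            )
        if progress_every and n % progress_every == 0:
            logger.info("recognized %d figures (%d hits so far)", n, len(rows))
    table = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return table.sort_values(["figure_id", "word_index", "ncbi_gene_id"], kind="mergesort").reset_index(drop=True)


def hits_to_json_records(hit_table: pd.DataFrame) -> list[dict]:
    """Per-figure gene-set records: {pmcid, figure_id, genes:[...]}."""
    records = []
    for (figure_id, pmcid), grp in hit_table.groupby(["figure_id", "pmcid"], sort=True):
        records.append(
            {
                "pmcid": pmcid or None,
                "figure_id": figure_id,
                "genes": sorted(int(g) for g in grp["ncbi_gene_id"].unique()),
            }
        )
    return records


def write_hits_json(hit_table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(hits_to_json_records(hit_table), fh, indent=1, sort_keys=True)
        fh.write("\n")
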