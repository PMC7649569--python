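"""Layered human gene-symbol lexicon.

The lexicon maps normalized symbol variants to official HGNC symbols and NCBI
Gene identifiers, layered in four tiers of decreasing authority:

1. ``hgnc_current`` — approved symbols,
2. ``hgnc_alias``  — synonym symbols,
3. ``hgnc_previous`` — retired symbols,
4. ``bioentities`` — conventional protein/complex/family names curated to
   official symbols (e.g. "NF-kB" -> NFKB1...).

Lookups return entries sorted by tier, so the matcher can prefer the most
authoritative interpretation of an ambiguous variant. All variants pass the
same character normalization as OCR words (:func:`pathfig.transforms.
normalize_characters`), making lookup keys directly comparable to transform
candidates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .transforms import normalize_characters

__all__ = [
    "TIER_ORDER",
    "LexiconEntry",
    "Lexicon",
    "build_lexicon",
    "read_stoplist",
    "default_stoplist",
]

logger = logging.getLogger(__name__)

TIER_ORDER = ("hgnc_current", "hgnc_alias", "hgnc_previous", "bioentities")

# Accepted header spellings for HGNC-style tables, in priority order.
_HGNC_COLUMNS = {
    "symbol": ("symbol", "approved symbol", "approved_symbol"),
    "alias": ("alias_symbol", "alias symbols", "alias_symbols", "aliases"),
    "previous": ("prev_symbol", "previous symbols", "prev_symbols", "previous_symbols"),
    "gene_id": ("entrez_id", "ncbi gene id", "ncbi_gene_id", "gene_id", "entrez gene id"),
}


@dataclass(frozen=True, order=True)
class LexiconEntry:
    """One variant -> gene mapping with its source tier."""

    variant: str
    official_symbol: str
    gene_id: int
    source: str

    def __post_init__(self) -> None:
        if self.gene_id <= 0:
            raise ValueError(f"gene_id must be positive, got {self.gene_id}")
        if self.source not in TIER_ORDER:
            raise ValueError(f"unknown lexicon tier {self.source!r}")


@dataclass
class Lexicon:
    """Multimap from normalized variant to lexicon entries, tier-ordered."""

    entries: dict[str, list[LexiconEntry]] = field(default_factory=dict)
    tier_order: tuple[str, ...] = TIER_ORDER

    def add(self, entry: LexiconEntry) -> None:
        bucket = self.entries.setdefault(entry.variant, [])
        if entry not in bucket:
            bucket.append(entry)
            bucket.sort(key=lambda e: (self.tier_order.index(e.source), e.official_symbol, e.gene_id))

    def lookup(self, variant: str) -> list[LexiconEntry]:
        """Entries for a normalized variant, best tier first ([] if none)."""
        return list(self.entries.get(variant, ()))

    def __contains__(self, variant: str) -> bool:
        return variant in self.entries

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def variants(self) -> Iterable[str]:
        return self.entries.keys()


def lookup(lex: Lexicon, variant: str) -> list[LexiconEntry]:
    """Module-level alias for :meth:`Lexicon.lookup`."""
    return lex.lookup(variant)


def read_stoplist(path) -> set[str]:
    """Read a stoplist file: one variant per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(normalize_characters(line))
    return out


def default_stoplist() -> set[str]:
    """The bundled stoplist: the 20 three-letter amino-acid codes.

    Residue annotations in figures (Tyr, His, Met ...) collide with gene
    aliases; excluding them trades a little recall for precision. Not applied
    unless requested.
    """
    src = resources.files("pathfig") / "data" / "aa_stoplist.txt"
    out = set()
    for line in src.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(line.upper())
    return out


def _find_column(columns: Iterable[str], wanted: tuple[str, ...], required: bool, role: str) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for name in wanted:
        if name in lowered:
            return lowered[name]
    if required:
        raise ValueError(f"HGNC-style table is missing a column for {role} (accepted: {wanted})")
    return None


def _split_list(value) -> list[str]:
    """Split a list-valued HGNC cell on '|' or ', ' (both accepted)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return []
    if "|" in text:
        parts = text.split("|")
    else:
        parts = text.split(",")
    return [p.strip() for p in parts if p.strip()]


def build_lexicon(
    hgnc_table,
    bioentities_table=None,
    stoplist: set[str] | None = None,
) -> Lexicon:
    """Build the layered lexicon from source tables.

    Parameters
    ----------
    hgnc_table
        Path to an HGNC-style TSV (or a DataFrame) with columns for the
        approved symbol, alias list, previous-symbol list and NCBI Gene ID.
        List-valued cells may be delimited by ``|`` or ``, ``.
    bioentities_table
        Optional path to a bioentities-style CSV (or DataFrame): first column
        the conventional name, remaining columns official symbol(s). Names
        mapping to symbols absent from the HGNC table are skipped with a
        warning.
    stoplist
        Variants to exclude from the lexicon entirely (already-normalized or
        raw; they are normalized here).

    Deterministic: identical inputs produce an identical entry set.
    """
    if isinstance(hgnc_table, pd.DataFrame):
        hgnc = hgnc_table.copy()
    else:
        hgnc = pd.read_csv(hgnc_table, sep="\t", dtype=str, keep_default_na=False)

    sym_col = _find_column(hgnc.columns, _HGNC_COLUMNS["symbol"], True, "approved symbol")
    alias_col = _find_column(hgnc.columns, _HGNC_COLUMNS["alias"], False, "alias symbols")
    prev_col = _find_column(hgnc.columns, _HGNC_COLUMNS["previous"], False, "previous symbols")
    id_col = _find_column(hgnc.columns, _HGNC_COLUMNS["gene_id"], True, "NCBI Gene ID")

    stop = {normalize_characters(s) for s in stoplist} if stoplist else set()

    lex = Lexicon()
    official_to_id: dict[str, int] = {}

    for _, row in hgnc.iterrows():
        symbol = str(row[sym_col]).strip()
        gid_raw = str(row[id_col]).strip()
        if not symbol or not gid_raw:
            continue
        gene_id = int(float(gid_raw))
        norm_symbol = normalize_characters(symbol)
        if not norm_symbol:
            continue
        official_to_id[norm_symbol] = gene_id
        if norm_symbol not in stop:
            lex.add(LexiconEntry(norm_symbol, symbol, gene_id, "hgnc_current"))
        for alias in _split_list(row[alias_col]) if alias_col else []:
            v = normalize_characters(alias)
            if v and v not in stop:
                lex.add(LexiconEntry(v, symbol, gene_id, "hgnc_alias"))
        for prev in _split_list(row[prev_col]) if prev_col else []:
            v = normalize_characters(prev)
            if v and v not in stop:
                lex.add(LexiconEntry(v, symbol, gene_id, "hgnc_previous"))

    if bioentities_table is not None:
        if isinstance(bioentities_table, pd.DataFrame):
            rows = bioentities_table.astype(str).values.tolist()
        else:
            with open(bioentities_table, newline="", encoding="utf-8") as fh:
                rows = [r for r in csv.reader(fh) if r]
        for row in rows:
            if not row or not row[0].strip():
                continue
            name = row[0].strip()
            variant = normalize_characters(name)
            if not variant or variant in stop:
                continue
            for target in row[1:]:
                target = target.strip()
                if not target or target.lower() == "nan":
                    continue
                norm_target = normalize_characters(target)
                gene_id = official_to_id.get(norm_target)
                if gene_id is None:
                    logger.warning(
                        "bioentities name %r maps to unknown official symbol %r; skipped",
                        name,
                        target,
                    )
                    continue
                lex.add(LexiconEntry(variant, target, gene_id, "bioentities"))

    return lex
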