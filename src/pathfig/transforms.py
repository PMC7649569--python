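"""Transform chain applied to OCR words before lexicon matching.

Pathway authors rarely write plain HGNC symbols: figures carry Greek letters
(``NF-κB``), phospho/tag decorations (``p-AKT``, ``CDK1-FLAG``), numerical
family ranges (``WNT1-5``) and slash-joined paralogs (``LATS1/2``), and OCR
itself confuses visually similar characters (``AKTI`` for ``AKT1``). Each
transform turns one raw word into a small set of candidate symbols; matching
against the lexicon is attempted after each round, so earlier (more
conservative) rounds win over later (more speculative) ones.

All rule tables (Greek map, confusion pairs, affix sets) are plain text files
bundled under :mod:`pathfig.data` and can be replaced by the user.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

__all__ = [
    "TransformRule",
    "TransformChain",
    "normalize_characters",
    "substitute_ocr_errors",
    "strip_decorations",
    "expand_multi",
    "candidate_rounds",
    "candidate_stream",
    "default_chain",
    "load_greek_map",
    "load_confusions",
    "load_affixes",
]

_DATA = resources.files("pathfig") / "data"

#: Unicode dash-like codepoints unified to ASCII "-".
_DASHES = "‐‑‒–—―−­"

#: Punctuation stripped from word boundaries.
_EDGE_PUNCT = "()[]{}.,:;*"


def _read_table_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8") if isinstance(path, (str, Path)) else path.read_text(encoding="utf-8")
    lines = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.lstrip().startswith("#"):
            continue
        lines.append(line)
    return lines


def load_greek_map(path=None) -> dict[str, str]:
    """Greek codepoint -> Latin replacement table (two-column TSV)."""
    src = path if path is not None else _DATA / "greek_map.tsv"
    mapping = {}
    for line in _read_table_lines(src):
        greek, latin = line.split("\t")
        mapping[greek] = latin
    return mapping


def load_confusions(path=None) -> list[tuple[str, str]]:
    """OCR confusion pairs (two-column TSV); substitutions run both ways."""
    src = path if path is not None else _DATA / "ocr_confusions.tsv"
    pairs = []
    for line in _read_table_lines(src):
        a, b = line.split("\t")
        pairs.append((a, b))
    return pairs


def load_affixes(prefixes_path=None, suffixes_path=None) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Decoration prefix/suffix sets (one affix per line, '#' comments)."""
    pre_src = prefixes_path if prefixes_path is not None else _DATA / "prefixes.txt"
    suf_src = suffixes_path if suffixes_path is not None else _DATA / "suffixes.txt"
    prefixes = tuple(_read_table_lines(pre_src))
    suffixes = tuple(_read_table_lines(suf_src))
    return prefixes, suffixes


_GREEK = load_greek_map()
_CONFUSIONS = load_confusions()
_PREFIXES, _SUFFIXES = load_affixes()


def normalize_characters(word: str, greek_map: dict[str, str] | None = None) -> str:
    """Canonicalize one raw OCR word.

    Uppercases, maps Greek letters to their conventional Latin replacement,
    unifies Unicode dashes to ``-``, strips surrounding punctuation
    (``()[]{}.,:;*``) and removes internal whitespace. Returns ``""`` when
    the word reduces to nothing (caller skips it). Idempotent.

    >>> normalize_characters("NF-κB,")
    'NF-KB'
    >>> normalize_characters("(p53)")
    'P53'
    """
    greek = greek_map if greek_map is not None else _GREEK
    out = []
    for ch in word:
        if ch.isspace():
            continue
        if ch in _DASHES:
            out.append("-")
            continue
        if ch in greek:  # lowercase Greek maps directly
            out.append(greek[ch])
            continue
        # uppercase first: e.g. µ (micro sign) uppercases into Greek Μ
        for up in ch.upper():
            out.append(greek.get(up, up))
    return "".join(out).strip(_EDGE_PUNCT)


def substitute_ocr_errors(
    word: str,
    confusions: list[tuple[str, str]] | None = None,
    max_substitutions: int = 1,
) -> list[str]:
    """Candidates correcting common OCR character confusions.

    Applies the bidirectional confusion table (default ``0<->O``, ``1<->I``,
    ``1<->L``, ``5<->S``, ``8<->B``) at up to ``max_substitutions`` positions.
    The unmodified word is always the first candidate.
    """
    pairs = confusions if confusions is not None else _CONFUSIONS
    alternatives: dict[str, set[str]] = {}
    for a, b in pairs:
        alternatives.setdefault(a, set()).add(b)
        alternatives.setdefault(b, set()).add(a)

    candidates = [word]
    seen = {word}
    positions = [i for i, ch in enumerate(word) if ch in alternatives]
    for r in range(1, max_substitutions + 1):
        for combo in itertools.combinations(positions, r):
            pools = [sorted(alternatives[word[i]]) for i in combo]
            for repls in itertools.product(*pools):
                chars = list(word)
                for i, repl in zip(combo, repls):
                    chars[i] = repl
                cand = "".join(chars)
                if cand and cand not in seen:
                    seen.add(cand)
                    candidates.append(cand)
    return candidates


def strip_decorations(
    word: str,
    prefixes: Iterable[str] | None = None,
    suffixes: Iterable[str] | None = None,
) -> list[str]:
    """Candidates with known decoration affixes removed.

    ``P-AKT`` yields ``AKT``; ``CDK1-FLAG`` yields ``CDK1``. Prefix-only,
    suffix-only and both-sides stripping are all emitted; the original word
    stays first. Affixes fire only on the curated sets, so hyphens inside
    real symbols are untouched.
    """
    pres = tuple(prefixes) if prefixes is not None else _PREFIXES
    sufs = tuple(suffixes) if suffixes is not None else _SUFFIXES

    candidates = [word]
    seen = {word}

    def _push(cand: str) -> None:
        if cand and cand not in seen:
            seen.add(cand)
            candidates.append(cand)

    no_prefix = word
    for p in pres:
        if word.startswith(p) and len(word) > len(p):
            no_prefix = word[len(p):]
            _push(no_prefix)
            break
    no_suffix = word
    for s in sufs:
        if word.endswith(s) and len(word) > len(s):
            no_suffix = word[: -len(s)]
            _push(no_suffix)
            break
    if no_prefix != word and no_suffix != word:
        both = no_prefix[: -(len(word) - len(no_suffix))]
        _push(both)
    return candidates


_RANGE_RE = re.compile(r"^(?P<stem>.*?[A-Z])(?P<a>\d+)-(?P<b>\d+)$")
_SLASH_NUM_RE = re.compile(r"^(?P<stem>.*?[A-Z])(?P<nums>\d+(?:/\d+)+)$")


def expand_multi(word: str, max_span: int = 20) -> list[str]:
    """Expand compact multi-gene notations into individual symbols.

    Handles numerical ranges (``WNT1-5`` -> WNT1..WNT5, ``TEAD1-4`` ->
    TEAD1..TEAD4), slash-joined paralog numbers (``LATS1/2`` -> LATS1,
    LATS2), and slash-joined full symbols (``YAP/TAZ`` -> YAP, TAZ). Ranges
    wider than ``max_span`` are left alone — families like WNT (19 members)
    must pass while page ranges like ``IL1-100`` must not. Returns ``[word]``
    when no notation applies.
    """
    m = _RANGE_RE.match(word)
    if m:
        a, b = int(m.group("a")), int(m.group("b"))
        if a < b and (b - a) < max_span:
            stem = m.group("stem")
            return [f"{stem}{i}" for i in range(a, b + 1)]
        return [word]

    m = _SLASH_NUM_RE.match(word)
    if m:
        stem = m.group("stem")
        nums = m.group("nums").split("/")
        out = []
        for n in nums:
            cand = f"{stem}{n}"
            if cand not in out:
                out.append(cand)
        return out

    if "/" in word:
        halves = word.split("/")
        if all(len(h) >= 2 and any(c.isalpha() for c in h) for h in halves):
            out = []
            for h in halves:
                if h not in out:
                    out.append(h)
            return out
    return [word]


@dataclass(frozen=True)
class TransformRule:
    """One named, pure transformation from a word to candidate strings."""

    name: str
    kind: str  # normalize | substitute | strip | expand
    func: Callable[[str], list[str]]

    def applies(self, word: str) -> bool:
        return len(self.apply(word)) > 1 or (self.apply(word) != [word])

    def apply(self, word: str) -> list[str]:
        return [c for c in self.func(word) if c]


@dataclass(frozen=True)
class TransformChain:
    """Ordered rules defining the matching rounds.

    Round 0 is always the normalized word itself; round *i* (1-based) is the
    output of ``rules[i-1]`` applied to the normalized word. ``max_candidates``
    caps the total stream size for pathological inputs.
    """

    rules: tuple[TransformRule, ...]
    max_candidates: int = 64

    def rounds(self, word: str) -> list[list[str]]:
        return candidate_rounds(word, self)


def default_chain(
    max_substitutions: int = 1,
    max_span: int = 20,
    max_candidates: int = 64,
) -> TransformChain:
    """The shipped chain: substitute -> strip -> expand (after normalization)."""
    rules = (
        TransformRule(
            "ocr_substitutions",
            "substitute",
            lambda w: substitute_ocr_errors(w, max_substitutions=max_substitutions),
        ),
        TransformRule("strip_decorations", "strip", strip_decorations),
        TransformRule("expand_multi", "expand", lambda w: expand_multi(w, max_span=max_span)),
    )
    return TransformChain(rules=rules, max_candidates=max_candidates)


def candidate_rounds(word: str, chain: TransformChain | None = None) -> list[list[str]]:
    """Candidates grouped by transform round, duplicates suppressed globally.

    Round 0 holds the normalized word; each later round holds one rule's new
    candidates. Empty normalization yields no rounds at all.
    """
    ch = chain if chain is not None else default_chain()
    norm = normalize_characters(word)
    if not norm:
        return []
    seen = {norm}
    rounds = [[norm]]
    budget = ch.max_candidates - 1
    for rule in ch.rules:
        if budget <= 0:
            break
        fresh = []
        for cand in rule.apply(norm):
            if cand not in seen and budget > 0:
                seen.add(cand)
                fresh.append(cand)
                budget -= 1
        rounds.append(fresh)
    return rounds


def candidate_stream(word: str, chain: TransformChain | None = None) -> list[str]:
    """Flat, ordered, duplicate-free candidate list for one raw OCR word."""
    return [c for rnd in candidate_rounds(word, chain) for c in rnd]
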