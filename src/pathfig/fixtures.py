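"""Synthetic test corpora with known ground truth.

Generates everything the pipeline consumes, fully determined by a seed: a
toy HGNC-style lexicon (with aliases, previous symbols and bioentities
names), OCR-text figures planted with decorated symbols, numerical ranges,
slash paralogs, Greek spellings and OCR-style character corruptions, plus
distractor words, figure metadata and annotation collections. Every planted
figure carries a :class:`PlantManifest` recording exactly which gene IDs its
recovery must yield, enabling exact end-to-end assertions without any
download or OCR engine.

All gene identifiers here are synthetic stand-ins for NCBI Gene IDs
(deterministic small integers), and the lexicon is a small synthetic excerpt
of human gene nomenclature — sufficient for the transform grammar, not a
real HGNC release.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import recognizer as _recognizer
from .enrichment import AnnotationCollection
from .figure_ocr import OcrDocument
from .lexicon import Lexicon, build_lexicon, default_stoplist
from .transforms import TransformChain, default_chain

__all__ = [
    "PlantManifest",
    "CorpusFixture",
    "toy_lexicon_frames",
    "make_corpus",
    "make_annotation_collection",
    "render_figure",
]

# Families with numbered members (for range/slash plants) and singletons.
_FAMILIES = {
    "WNT": list(range(1, 12)),
    "TEAD": [1, 2, 3, 4],
    "LATS": [1, 2],
    "AKT": [1, 2, 3],
    "CDK": [1, 2, 4, 5, 6],
    "SMAD": [2, 3, 4],
    "STK": [3, 4],
    "MOB1": ["A", "B"],
}
_SINGLETONS = [
    "TP53", "EGFR", "MTOR", "YAP1", "WWTR1", "NFKB1", "RELA", "SAV1",
    "NF2", "WWC1", "TNF", "KRAS", "RAF1", "PIK3CA", "MAP2K1", "CTNNB1",
    "TGFB1", "NOTCH1", "JAK2", "STAT3", "IL6", "HIF1A", "VEGFA", "IFNG",
    "MAPK1", "MAPK3", "MAPK8", "MAPK14", "TYR",
]
_ALIASES = {
    "AKT1": ["AKT", "PKB"],
    "MAPK1": ["ERK2", "p42"],
    "MAPK3": ["ERK1", "p44"],
    "TP53": ["p53"],
    "YAP1": ["YAP"],
    "WWTR1": ["TAZ"],
    "STK4": ["MST1"],
    "STK3": ["MST2"],
    "NF2": ["merlin"],
    "WWC1": ["KIBRA"],
}
_PREVIOUS = {
    "MAPK1": ["PRKM1"],
    "MAPK3": ["PRKM3"],
}

# Conventional names mapped to official symbols; multi-gene rows exercise the
# family/complex path (kept in the lexicon, dropped as ambiguous by the
# matcher, so they are never planted as expected hits).
_BIOENTITIES = [
    ("NF-κB", ["NFKB1"]),
    ("TGF-β", ["TGFB1"]),
    ("IFN-γ", ["IFNG"]),
    ("ERK", ["MAPK1", "MAPK3"]),
]

# Distractor vocabulary guaranteed disjoint from the toy lexicon, plus the
# amino-acid codes that genuinely collide with gene symbols/aliases.
_DISTRACTORS = [
    "CELL", "MEMBRANE", "NUCLEUS", "CYTOPLASM", "ATP", "DNA", "RNA",
    "LIGAND", "RECEPTOR", "SIGNAL", "GROWTH", "APOPTOSIS", "STRESS",
    "GLYCOLYSIS", "PROLIFERATION", "SURVIVAL", "INFLAMMATION", "BINDING",
]
_AA_DISTRACTORS = ["Tyr", "His", "Met", "Ser", "Thr"]

_PREFIX_DECORATIONS = ["p-", "phospho-", "GFP-", "FLAG-", "HA-"]
_SUFFIX_DECORATIONS = ["-P", "-FLAG", "-GFP", "-HA", "-UB"]

_CONFUSION_FORWARD = {"0": "O", "1": "I", "5": "S", "8": "B"}


@dataclass(frozen=True)
class PlantManifest:
    """Ground truth for one synthetic figure.

    ``planted`` pairs each display string with the gene IDs its recovery must
    yield; ``collision_gene_ids`` lists genes that colliding amino-acid
    distractors legitimately add when the stoplist is off.
    """

    figure_id: str
    planted: tuple[tuple[str, tuple[int, ...]], ...]
    distractors: tuple[str, ...]
    collision_gene_ids: frozenset[int]
    pmcid: str
    year: int
    seed: int

    @property
    def expected_gene_ids(self) -> frozenset[int]:
        return frozenset(g for _, gids in self.planted for g in gids)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.planted) + self.distractors


@dataclass
class CorpusFixture:
    """A complete synthetic corpus: manifests, documents, lexicon, metadata."""

    manifests: list[PlantManifest]
    documents: list[OcrDocument]
    hgnc: pd.DataFrame
    bioentities: pd.DataFrame
    metadata: pd.DataFrame

    def build_lexicon(self, stoplist: set[str] | None = None) -> Lexicon:
        return build_lexicon(self.hgnc, self.bioentities, stoplist=stoplist)

    def write(self, directory) -> None:
        """Write all fixture artifacts in the formats the pipeline consumes."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.hgnc.to_csv(d / "hgnc.tsv", sep="\t", index=False)
        self.bioentities.to_csv(d / "bioentities.csv", index=False, header=False)
        self.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
        rows = []
        for doc in self.documents:
            rows.append(
                {
                    "figure_id": doc.figure_id,
                    "pmcid": doc.pmcid or "",
                    "year": doc.year if doc.year is not None else "",
                    "ocr_text": " ".join(doc.words),
                }
            )
        pd.DataFrame(rows).to_csv(d / "ocr_text.tsv", sep="\t", index=False)


def _official_symbols() -> list[str]:
    symbols = list(_SINGLETONS)
    for stem, members in _FAMILIES.items():
        for m in members:
            sym = f"{stem}{m}"
            if sym not in symbols:
                symbols.append(sym)
    return sorted(set(symbols))


def toy_lexicon_frames() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The toy HGNC-style table and bioentities table (synthetic gene IDs).

    Gene IDs are assigned deterministically (1001, 1002, ... in sorted symbol
    order); the lexicon is closed over everything :func:`make_corpus` plants.
    """
    symbols = _official_symbols()
    rows = []
    for i, sym in enumerate(symbols):
        rows.append(
            {
                "symbol": sym,
                "alias_symbol": "|".join(_ALIASES.get(sym, [])),
                "prev_symbol": "|".join(_PREVIOUS.get(sym, [])),
                "entrez_id": 1001 + i,
            }
        )
    hgnc = pd.DataFrame(rows)
    be_rows = [[name, *targets] for name, targets in _BIOENTITIES]
    width = max(len(r) for r in be_rows)
    be_rows = [r + [""] * (width - len(r)) for r in be_rows]
    bioentities = pd.DataFrame(be_rows)
    return hgnc, bioentities


def _gene_ids(hgnc: pd.DataFrame) -> dict[str, int]:
    return {row["symbol"]: int(row["entrez_id"]) for _, row in hgnc.iterrows()}


def _maybe_decorate(rng: random.Random, display: str, decoration_rate: float) -> str:
    if rng.random() < decoration_rate:
        if rng.random() < 0.5:
            return rng.choice(_PREFIX_DECORATIONS) + display
        return display + rng.choice(_SUFFIX_DECORATIONS)
    return display


def _maybe_corrupt(rng: random.Random, display: str, confusion_rate: float) -> str:
    if rng.random() >= confusion_rate:
        return display
    positions = [i for i, ch in enumerate(display) if ch in _CONFUSION_FORWARD]
    if not positions:
        return display
    i = rng.choice(positions)
    return display[:i] + _CONFUSION_FORWARD[display[i]] + display[i + 1 :]


def make_corpus(
    n_figures: int = 50,
    genes_per_figure: tuple[int, int] = (3, 12),
    decoration_rate: float = 0.5,
    range_rate: float = 0.3,
    confusion_rate: float = 0.1,
    amino_acid_rate: float = 0.15,
    n_distractors: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> CorpusFixture:
    """Generate a planted corpus, byte-reproducible from the parameters and seed.

    Each figure plants ``genes_per_figure`` draws; with probability
    ``range_rate`` a draw is a multi-gene token (range like ``TEAD1-4`` or
    slash like ``LATS1/2``), otherwise a single symbol or alias, decorated
    with probability ``decoration_rate`` and OCR-corrupted with probability
    ``confusion_rate``. Amino-acid distractors (colliding with gene symbols)
    are added with probability ``amino_acid_rate`` per figure and recorded in
    the manifest's collision budget. Every display string is validated at
    plant time to recover exactly its expected gene IDs, so manifests are
    correct by construction.
    """
    for rate in (decoration_rate, range_rate, confusion_rate, amino_acid_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
    rng = random.Random(seed)
    hgnc, bioentities = toy_lexicon_frames()
    ids = _gene_ids(hgnc)
    lex = build_lexicon(hgnc, bioentities)
    chain = default_chain()
    stop = default_stoplist()

    # pools
    plantable_singles: list[tuple[str, int]] = []
    for sym, gid in ids.items():
        if sym in stop:
            continue  # never plant stoplisted symbols as genuine genes
        plantable_singles.append((sym, gid))
        for alias in _ALIASES.get(sym, []):
            plantable_singles.append((alias, gid))
        for prev in _PREVIOUS.get(sym, []):
            plantable_singles.append((prev, gid))
    for name, targets in _BIOENTITIES:
        if len(targets) == 1:
            plantable_singles.append((name, ids[targets[0]]))
    plantable_singles.sort()

    range_families = [(stem, members) for stem, members in sorted(_FAMILIES.items())
                      if all(isinstance(m, int) for m in members)]

    manifests: list[PlantManifest] = []
    documents: list[OcrDocument] = []
    meta_rows = []
    lo, hi = genes_per_figure
    for i in range(n_figures):
        fig_seed = rng.randrange(2**31)
        fig_rng = random.Random(fig_seed)
        figure_id = f"fig{i:04d}"
        pmcid = f"PMC{900000 + i // 2}"  # two figures per synthetic paper
        year = fig_rng.randint(1995, 2019)
        n_genes = fig_rng.randint(lo, hi)

        planted: list[tuple[str, tuple[int, ...]]] = []
        used_ids: set[int] = set()
        attempts = 0
        while len(planted) < n_genes and attempts < n_genes * 20:
            attempts += 1
            if fig_rng.random() < range_rate:
                stem, members = fig_rng.choice(range_families)
                # pick a consecutive run of >= 2 members
                runs = [
                    (a_idx, b_idx)
                    for a_idx in range(len(members))
                    for b_idx in range(a_idx + 1, len(members))
                    if members[b_idx] - members[a_idx] == b_idx - a_idx
                ]
                a_idx, b_idx = fig_rng.choice(runs)
                a, b = members[a_idx], members[b_idx]
                gids = tuple(ids[f"{stem}{m}"] for m in members[a_idx : b_idx + 1])
                if fig_rng.random() < 0.5 and b_idx - a_idx == 1:
                    display = f"{stem}{a}/{b}"
                else:
                    display = f"{stem}{a}-{b}"
            else:
                sym, gid = fig_rng.choice(plantable_singles)
                gids = (gid,)
                display = _maybe_decorate(fig_rng, sym, decoration_rate)
                if display == sym:
                    display = _maybe_corrupt(fig_rng, display, confusion_rate)
            if set(gids) & used_ids:
                continue
            gids = tuple(sorted(gids))
            # plant-time validation: the token must recover exactly its genes
            got = tuple(sorted(g for _, _, g, _ in _recognizer.recognize_word(display, chain, lex)))
            if got != gids:
                continue  # corruption/decoration made the token unrecoverable; retry
            used_ids.update(gids)
            planted.append((display, gids))

        n_dis = fig_rng.randint(*n_distractors)
        distractors = [fig_rng.choice(_DISTRACTORS) for _ in range(n_dis)]
        collision_ids: set[int] = set()
        if fig_rng.random() < amino_acid_rate:
            aa = fig_rng.choice(_AA_DISTRACTORS)
            distractors.append(aa)
            for _, _, gid, _ in _recognizer.recognize_word(aa, chain, lex):
                collision_ids.add(gid)
        fig_rng.shuffle(distractors)

        manifest = PlantManifest(
            figure_id=figure_id,
            planted=tuple(planted),
            distractors=tuple(distractors),
            collision_gene_ids=frozenset(collision_ids),
            pmcid=pmcid,
            year=year,
            seed=fig_seed,
        )
        manifests.append(manifest)

        words = list(manifest.words)
        fig_rng.shuffle(words)
        documents.append(
            OcrDocument(figure_id=figure_id, words=tuple(words), pmcid=pmcid, year=year, provenance="fixture")
        )
        meta_rows.append(
            {
                "figure_id": figure_id,
                "pmcid": pmcid,
                "year": year,
                "figure_title": f"Synthetic pathway figure {i}",
                "caption": f"Planted figure with {len(planted)} gene tokens.",
            }
        )

    metadata = pd.DataFrame(meta_rows)
    return CorpusFixture(
        manifests=manifests,
        documents=documents,
        hgnc=hgnc,
        bioentities=bioentities,
        metadata=metadata,
    )


def make_annotation_collection(
    universe: set[int] | None = None,
    n_terms: int = 12,
    term_size: tuple[int, int] = (5, 15),
    seed: int = 0,
    name: str = "toy_diseases",
) -> AnnotationCollection:
    """A synthetic disease-style annotation collection over the toy genes.

    Term labels include singular/plural pairs (Tumor/Tumors) so the top-term
    deduplication path is exercised.
    """
    rng = random.Random(seed)
    if universe is None:
        hgnc, _ = toy_lexicon_frames()
        universe = set(_gene_ids(hgnc).values())
    pool = sorted(universe)
    labels = [
        "Tumor", "Tumors", "Infection", "Defects", "Diabetes", "Hypoxia",
        "Depression", "Obesity", "Ischemia", "Atherosclerosis", "Cancer",
        "Melanoma", "Cardiomyopathy", "Arthritis",
    ]
    terms = {}
    for t in range(n_terms):
        size = rng.randint(*term_size)
        size = min(size, len(pool))
        genes = frozenset(rng.sample(pool, size))
        label = labels[t % len(labels)]
        terms[f"DOID:{t:04d}"] = (label, genes)
    return AnnotationCollection(name=name, terms=terms, universe=frozenset(pool))


def render_figure(manifest: PlantManifest, out_path=None, font_size: int = 24,
                  width: int = 800, margin: int = 20):
    """Render a manifest as a high-contrast black-on-white label image.

    Labels are laid out row-wise without overlap; pixel output is a pure
    function of the manifest (its seed fixes the word order). Intended for
    OCR round-trip exercises when an engine is available.
    """
    from PIL import Image, ImageDraw, ImageFont

    rng = random.Random(manifest.seed)
    words = list(manifest.words)
    rng.shuffle(words)
    try:
        font = ImageFont.load_default(size=font_size)
    except TypeError:  # older Pillow
        font = ImageFont.load_default()

    line_h = font_size + 12
    rows: list[list[str]] = [[]]
    x = margin
    dummy = ImageDraw.Draw(Image.new("L", (1, 1), 255))
    for w in words:
        w_px = dummy.textlength(w, font=font)
        if x + w_px > width - margin and rows[-1]:
            rows.append([])
            x = margin
        rows[-1].append(w)
        x += w_px + 30
    height = margin * 2 + line_h * len(rows)
    img = Image.new("L", (width, height), 255)
    draw = ImageDraw.Draw(img)
    y = margin
    for row in rows:
        x = margin
        for w in row:
            draw.text((x, y), w, fill=0, font=font)
            x += draw.textlength(w, font=font) + 30
        y += line_h
    if out_path is not None:
        img.save(out_path)
    return img
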