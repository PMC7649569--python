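"""OCR document acquisition.

The pipeline consumes one :class:`OcrDocument` per figure: the ordered list
of newline- and space-delimited words an OCR engine produced for that image.
The engine itself is an injected callable (``image -> text``), never a
dependency — everything downstream of word isolation is testable from plain
text fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import pandas as pd

__all__ = [
    "OcrDocument",
    "OcrEngineUnavailableError",
    "words_from_text",
    "words_from_image",
    "documents_from_tsv",
    "documents_from_dir",
]


class OcrEngineUnavailableError(RuntimeError):
    """Raised when image input is requested but no OCR engine was injected."""


@dataclass(frozen=True)
class OcrDocument:
    """One figure's OCR words plus identifiers.

    ``provenance`` records whether the words came from a live engine or a
    pre-extracted text fixture.
    """

    figure_id: str
    words: tuple[str, ...]
    pmcid: str | None = None
    year: int | None = None
    provenance: str = "fixture"  # engine | fixture

    def __post_init__(self) -> None:
        if not self.figure_id:
            raise ValueError("figure_id must be non-empty")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"implausible year {self.year}")


def words_from_text(
    figure_id: str,
    ocr_text: str,
    pmcid: str | None = None,
    year: int | None = None,
    provenance: str = "fixture",
) -> OcrDocument:
    """Split raw OCR text into words on any whitespace run, order preserved."""
    words = tuple(ocr_text.split())
    return OcrDocument(figure_id=figure_id, words=words, pmcid=pmcid, year=year, provenance=provenance)


def words_from_image(
    figure_id: str,
    image,
    engine: Callable[[object], str] | None = None,
    pmcid: str | None = None,
    year: int | None = None,
) -> OcrDocument:
    """Run one image through an injected OCR engine.

    ``image`` may be a path or a ``PIL.Image.Image``; ``engine`` is any
    callable mapping an image to its text (e.g. ``pytesseract.image_to_string``
    where installed). Without an engine a capability error directs the caller
    to text fixtures.
    """
    if engine is None:
        raise OcrEngineUnavailableError(
            "no OCR engine injected; pass engine=<callable image -> text> "
            "or use text fixtures via words_from_text/documents_from_tsv"
        )
    if isinstance(image, (str, Path)):
        from PIL import Image, UnidentifiedImageError

        try:
            with Image.open(image) as im:
                im.load()
                text = engine(im)
        except (UnidentifiedImageError, OSError) as exc:
            raise ValueError(f"cannot decode image {image!r}: {exc}") from exc
    else:
        text = engine(image)
    return words_from_text(figure_id, text, pmcid=pmcid, year=year, provenance="engine")


def documents_from_tsv(path) -> Iterator[OcrDocument]:
    """Read a fixture TSV with columns figure_id, ocr_text (+ optional pmcid, year)."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "figure_id" not in table.columns or "ocr_text" not in table.columns:
        raise ValueError("fixture TSV needs columns 'figure_id' and 'ocr_text'")
    for _, row in table.iterrows():
        year = int(row["year"]) if "year" in table.columns and row["year"] else None
        pmcid = row["pmcid"] if "pmcid" in table.columns and row["pmcid"] else None
        yield words_from_text(row["figure_id"], row["ocr_text"], pmcid=pmcid, year=year)


def documents_from_dir(directory) -> Iterator[OcrDocument]:
    """Read one raw OCR text file per figure (*.txt; stem is the figure id)."""
    for path in sorted(Path(directory).glob("*.txt")):
        yield words_from_text(path.stem, path.read_text(encoding="utf-8"))
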