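"""Pipeline configuration.

One YAML file (or keyword overrides) drives both pipeline phases. Unknown
keys are rejected so typos fail loudly; the effective configuration is
echoed to the log at startup.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults for the full pipeline; every field is overridable from YAML."""

    lexicon_path: str | None = None        # HGNC-style TSV
    bioentities_path: str | None = None    # bioentities-style CSV
    stoplist_path: str | None = None       # custom stoplist file
    use_default_stoplist: bool = False     # amino-acid codes, off by default
    max_substitutions: int = 1             # OCR-confusion edits per word
    max_span: int = 20                     # widest numerical range expanded
    max_candidates: int = 64               # candidate-stream cap per word
    min_genes_sets: int = 7                # per-figure unique-gene cutoff (coverage)
    min_genes_enrichment: int = 10         # stricter cutoff for enrichment use
    min_genes_term: int = 7                # annotation-term size cutoff
    alpha: float = 0.05                    # BH FDR significance threshold
    ci_method: str = "wald"                # wald | wilson
    ci_confidence: float = 0.97
    linkage: str = "average"
    cluster_distance: str = "jaccard_distance"
    seed: int = 0

    def echo(self) -> None:
        logger.info("effective configuration: %s", asdict(self))


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config, apply overrides, reject unknown keys."""
    known = {f.name for f in fields(PipelineConfig)}
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(raw)
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**values)
    cfg.echo()
    return cfg
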