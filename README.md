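# pathfig

Gene-content extraction from pathway-figure OCR text, and analytics over the
extracted gene sets.

Most pathway knowledge in the biomedical literature is published as static
figures — signaling cascades, metabolic cycles, regulatory diagrams — whose
gene content never reaches the paper's text, text-mining pipelines, or
curated pathway databases. `pathfig` implements the post-OCR half of mining
that content: given the words an OCR engine reads off a figure, it recovers
the human genes the figure depicts, and turns a corpus of figures into
annotated, comparable gene sets. It is aimed at curators and bioinformaticians
building figure-derived gene-set resources, and at anyone who needs a tested,
deterministic reference implementation of this extraction strategy.

## What it does

**Recognition.** Each OCR word passes through a chain of transforms, with a
lexicon match attempted after every round; the first matching round wins:

1. *character normalization* — uppercasing, Greek→Latin (`NF-κB` → `NF-KB`),
   Unicode-dash unification, punctuation stripping;
2. *OCR-error substitution* — the confusion pairs `0↔O, 1↔I, 1↔L, 5↔S, 8↔B`
   (`AKTI` → `AKT1`);
3. *decoration stripping* — curated prefix/suffix sets for phospho marks and
   epitope tags (`p-AKT` → `AKT`, `CDK1-FLAG` → `CDK1`);
4. *multi-gene expansion* — numerical ranges and slash paralogs
   (`WNT1-5` → WNT1…WNT5, `LATS1/2` → LATS1, LATS2, `YAP/TAZ` → YAP, TAZ).

Candidates are matched against a four-tier lexicon — current HGNC symbols,
aliases, previous symbols, and conventional "bioentities" names mapped to
official symbols — keeping only the best tier per candidate and dropping
variants that remain ambiguous (one symbol, several genes) at that tier.
Every hit records the raw word, matched variant, official symbol, NCBI Gene
ID and lexicon tier.

**Analytics.** Hit tables become per-figure gene sets (unique NCBI Gene IDs),
which support: size filtering (`≥ 7` genes for coverage analyses, `≥ 10` for
enrichment use), exact-duplicate and strict-containment detection, directional
overlap (`|A∩B|/|A|`) and Jaccard (`|A∩B|/|A∪B|`) matrices with hierarchical
clustering and Newick/heatmap output, hypergeometric overrepresentation
against GMT or disease-association collections with Benjamini–Hochberg FDR
(the upper tail `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`), greedy
non-redundant top-term ranking, and corpus statistics (instances vs unique
genes, figure-vs-text comparison, database novelty, precision/recall/MCC,
Wald and Wilson binomial intervals, cloning-to-pathway year spans).

**Synthetic corpora.** `pathfig.fixtures` generates seeded corpora with plant
manifests — every figure records exactly which gene IDs its decorated,
range-compressed, OCR-corrupted tokens must yield — so the whole pipeline is
testable end to end with no downloads and no OCR engine. An OCR engine is an
*injected callable*, never a dependency; raster input (`words_from_image`)
raises a clear capability error without one.

## Worked example

```python
from pathfig import build_lexicon, recognize_corpus, words_from_text
from pathfig.fixtures import toy_lexicon_frames   # synthetic demo lexicon

hgnc, bioentities = toy_lexicon_frames()
lex = build_lexicon(hgnc, bioentities)
docs = [
    words_from_text("fig1", "p-AKT WNT1-5 TP53 nucleus", pmcid="PMC123"),
    words_from_text("fig2", "LATS1/2 NF-κB, CDK1-FLAG ligand", pmcid="PMC124"),
]
hits = recognize_corpus(docs, lex=lex)
print(hits[["figure_id", "raw_word", "matched_variant", "official_symbol",
            "ncbi_gene_id", "lexicon_source"]].to_string(index=False))
```

prints

```
figure_id  raw_word matched_variant official_symbol  ncbi_gene_id lexicon_source
     fig1     p-AKT             AKT            AKT1          1001     hgnc_alias
     fig1    WNT1-5            WNT1            WNT1          1048   hgnc_current
     fig1    WNT1-5            WNT2            WNT2          1051   hgnc_current
     fig1    WNT1-5            WNT3            WNT3          1052   hgnc_current
     fig1    WNT1-5            WNT4            WNT4          1053   hgnc_current
     fig1    WNT1-5            WNT5            WNT5          1054   hgnc_current
     fig1      TP53            TP53            TP53          1045   hgnc_current
     fig2   LATS1/2           LATS1           LATS1          1016   hgnc_current
     fig2   LATS1/2           LATS2           LATS2          1017   hgnc_current
     fig2    NF-κB,           NF-KB           NFKB1          1027    bioentities
     fig2 CDK1-FLAG            CDK1            CDK1          1004   hgnc_current
```

`p-AKT` resolved through the strip round to the alias `AKT`; `WNT1-5`
expanded to five family members; `NF-κB,` normalized through the Greek map
and matched a bioentities name; the distractor words (`nucleus`, `ligand`)
matched nothing. Collapsing hits with `pathfig.genesets.build_sets` gives one
unique-gene set per figure (7 genes for `fig1`, 4 for `fig2`); the gene IDs
here are the demo lexicon's synthetic stand-ins for NCBI Gene IDs.

The same pipeline runs from the shell:

```sh
pathfig make-fixtures --n-figures 50 --seed 1 --out-dir fx/
pathfig recognize fx/ocr_text.tsv --lexicon fx/hgnc.tsv \
    --bioentities fx/bioentities.csv --out-dir out/
pathfig analyze out/hits.tsv --metadata fx/metadata.tsv \
    --min-genes 10 --out-dir out/analysis/
```

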