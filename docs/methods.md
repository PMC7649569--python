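# Methods

## The recognition model

The pipeline treats gene recognition in pathway figures as post-OCR string
normalization against a layered nomenclature lexicon, not as statistical NER.
Each OCR word is processed independently; layout, panel structure and
multi-word names are not modelled (a symbol split across lines, e.g. "NF"
then "κB", is not reassembled).

Candidate generation runs in rounds, and matching is attempted after every
round. Round 0 is the normalized word; the later rounds apply, in order, OCR
confusion substitutions, decoration stripping, and multi-gene expansion to
the normalized word. The **first round producing at least one lexicon match
wins** and later rounds are discarded for that word. This stop rule prevents
over-generation: a word that is itself a valid symbol must not also spawn
hits from speculative edits of itself, and later rounds are increasingly
speculative. The cost is that a word can contribute genes from only one
round (e.g. a token that is simultaneously a valid symbol *and* a range
abbreviation resolves to the symbol).

Within a matched candidate, only the best lexicon tier is kept
(current > alias > previous > bioentities). If the best tier still maps the
variant to more than one gene — an ambiguous alias or a multi-member family
name such as "ERK" — the candidate is dropped and logged rather than
multi-emitted. This prefers precision over recall and keeps per-gene figure
counts interpretable as "this gene was depicted", at the cost of losing
genuinely intended family references.

Hits are recorded per word occurrence (instances); unique-gene semantics are
applied only when sets are built, always keyed by NCBI Gene ID, never by
symbol string.

## Transform tables

The transform categories are fixed; the tables driving them are editable
text files under `src/pathfig/data/`:

| table | default | role |
|---|---|---|
| `greek_map.tsv` | full Greek alphabet → Latin initials (α→A, β→B, κ→K, …) | character normalization |
| `ocr_confusions.tsv` | 0↔O, 1↔I, 1↔L, 5↔S, 8↔B | OCR-error substitution |
| `prefixes.txt` | P-, PP-, PHOSPHO-, AC-, MYC-, HA-, GST-, GFP-, FLAG- | decoration stripping |
| `suffixes.txt` | -P, -FLAG, -GFP, -HA, -MYC, -TAG, -UB | decoration stripping |
| `aa_stoplist.txt` | the 20 three-letter amino-acid codes | optional lexicon stoplist |

Normalization uppercases before Greek mapping (characters such as µ
uppercase *into* Greek letters), unifies Unicode dashes to `-`, strips the
edge punctuation `()[]{}.,:;*` and removes internal whitespace; it is
idempotent by construction and property-tested as such.

Hyphen ambiguity is resolved structurally: strips fire only on the curated
affix sets, range expansion only on trailing digit–dash–digit patterns, and
both candidate sets are emitted in their respective rounds, letting the
lexicon disambiguate (`CDK1-FLAG` strips; `WNT1-5` expands; `NF-KB` does
neither).

Numerical parameters, all configurable:

* `max_substitutions = 1` confusion edits per word — one corrupt character
  per symbol is the common case; two edits explode the candidate space and
  the false-match risk.
* `max_span = 20` for range expansion — wide enough for the largest numbered
  human gene families that appear as ranges (WNT has 19 members), narrow
  enough to reject page-range artefacts like `IL1-100`.
* `max_candidates = 64` caps the candidate stream for pathological inputs.

## Lexicon

Built from an HGNC-style TSV (approved symbol, alias list, previous list,
NCBI Gene ID; list cells delimited by `|` or `,`) plus an optional
bioentities-style CSV (conventional name, official symbol(s)). All variants
pass the same character normalization as OCR words, so lookup is exact
string equality. A bioentities name mapping to several genes produces one
entry per member, all returned at the bioentities tier (and hence dropped by
the matcher as ambiguous — deliberate, see above). Names mapping to symbols
absent from the HGNC table are skipped with a warning.

The amino-acid stoplist addresses the one systematic false-positive class of
this approach: residue annotations (Tyr15, His, Met) that collide with gene
symbols or aliases. It ships but is **off by default**, since excluding the
codes also silences genuine mentions of those genes (e.g. TYR/tyrosinase);
enable it with `--use-default-stoplist` when figures are residue-heavy.

## Gene-set analytics

* **Size filters.** `≥ 7` unique genes marks a set as biologically
  characterizable; `≥ 10` is the stricter default for enrichment use, where
  very small sets destabilize overrepresentation statistics. Thresholds are
  inclusive.
* **Redundancy.** Exact duplicates are groups of figures with identical gene
  content; containment is a *strict* subset relation, so the two categories
  are disjoint by construction.
* **Similarity.** Directional overlap `|A∩B|/|A|` (a subset scores 1 on its
  own row against any superset) and Jaccard `|A∩B|/|A∪B|`; both computed by
  one incidence-matrix product and verified against naive set arithmetic in
  tests.
* **Clustering** is agglomerative on `1 − similarity`; the default is
  average linkage on Jaccard distance, with the directional-overlap variant
  (symmetrized by the pairwise max, so nesting reads as closeness) available
  by option. No claim is made that these defaults reproduce any particular
  published dendrogram; they are documented conventions.

## Enrichment

One-sided hypergeometric upper tail (`scipy.stats.hypergeom.sf(k−1, N, K,
n)`) — the standard overrepresentation test; tested against exhaustive draw
enumeration for every universe size ≤ 12. Multiple testing is controlled by
Benjamini–Hochberg within each gene set across terms at FDR < 0.05 by
default; significance procedure and threshold are package conventions, as is
the default universe (the union of all genes in the annotation collection,
overridable). Terms with fewer than 7 genes are removed before testing. The
per-set top term is the smallest FDR, ties broken by larger overlap then
lexicographic term id. The non-redundant top-term ranking merges
singular/plural labels (trailing-S rule, applied only when both forms
occur), then greedily assigns each item to the term covering the most
not-yet-counted items, ten picks, remainder counted as "Other".

## Corpus statistics

`mean_genes_per_figure` defaults to instance counting — total recognized
instances divided by gene-containing figures — with a unique-genes-per-figure
mode by flag. The binomial proportion interval defaults to the Wald
half-width `z·sqrt(p(1−p)/n)` with Wilson available for small samples or
extreme proportions. Classifier metrics return `None` for undefined
denominators rather than coercing to zero; the MCC implementation is
cross-checked against scikit-learn in tests. Cloning-to-pathway spans take
the earliest year-annotated figure per gene minus a user-supplied event
year; genes without an event year are excluded and negative spans are
retained but flagged.

## Synthetic corpora: what they do and do not show

`fixtures.make_corpus` plants, per figure, a mix of bare symbols, aliases,
previous symbols, bioentities names (including Greek spellings), decorated
tokens, single-character OCR corruptions, numerical ranges and slash
paralogs, plus distractor words — including, at a configurable rate,
amino-acid codes that genuinely collide with the toy lexicon. Defaults:
50 figures, 3–12 genes each, decoration rate 0.5, range rate 0.3, confusion
rate 0.1, amino-acid distractor rate 0.15; the end-to-end acceptance run
uses 200 figures at the same rates. Every token is validated at plant time
to recover exactly its intended genes, so manifests are correct by
construction, and corpora are byte-reproducible from (parameters, seed).
The toy lexicon's gene IDs are deterministic synthetic integers, not real
NCBI IDs.

The grammar covers exactly the transform classes the pipeline ships, so
planted recovery being 100% shows the chain and matcher are faithful to
their own rules — it does **not** estimate recall on real figures, where
OCR noise, fonts, layout and out-of-lexicon species symbols dominate.
Rendered-image fixtures (`render_figure`, high-contrast black-on-white
labels, deterministic pixels) support OCR round-trip exercises, but only
when an OCR engine is injected; no engine ships with the package.

## Numerical and degenerate-input choices

Hit tables sort by (figure_id, word_index, gene_id) with a stable sort;
duplicate figure ids are input errors. Empty normalization results drop a
word before matching. Empty gene sets are rejected by the overlap matrix;
fewer than two sets by clustering. An empty corpus yields an undefined
(None) mean rather than zero. All CLI runs are deterministic; the only
randomness in the package is in fixture generation, fully governed by the
seed.

## Limitations

Single-word matching only; no interaction/edge extraction; human lexicon
only (the design does not preclude other species, none ship); no
ontology-aware propagation of GO terms; no GSEA-style ranked enrichment;
figure-vs-text comparison consumes static text-mining tables rather than
live services.
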