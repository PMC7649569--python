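# Decoration prefixes stripped from normalized words (one per line, with the
# trailing hyphen). Covers phosphorylation/acetylation marks and epitope tags
# habitually prefixed to gene symbols in pathway figures.
P-
PP-
PHOSPHO-
AC-
MYC-
HA-
GST-
GFP-
FLAG-
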