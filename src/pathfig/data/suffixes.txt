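# Decoration suffixes stripped from normalized words (one per line, with the
# leading hyphen): epitope tags, phospho marks and ubiquitin annotations.
-P
-FLAG
-GFP
-HA
-MYC
-TAG
-UB
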