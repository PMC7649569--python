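# Bidirectional OCR confusion pairs: each line lists two characters that OCR
# engines commonly swap in gene symbols. Substitution candidates are generated
# in both directions.
0	O
1	I
1	L
5	S
8	B
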