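# Three-letter amino-acid codes. These collide with gene aliases when figures
# annotate residues (Tyr15, His, Met ...), the one problematic false-positive
# class of lexicon matching on pathway figures. Off by default; enable with
# the stoplist option.
ALA
ARG
ASN
ASP
CYS
GLN
GLU
GLY
HIS
ILE
LEU
LYS
MET
PHE
PRO
SER
THR
TRP
TYR
VAL
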