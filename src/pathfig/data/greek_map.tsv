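# Greek character -> Latin replacement used during character normalization.
# Lowercase and uppercase codepoints are listed separately so the table is
# trivially editable; replacements follow the initial of the Greek letter name
# as conventionally used in gene symbols (NF-kB, TGF-b, IFN-g ...).
α	A
β	B
γ	G
δ	D
ε	E
ζ	Z
η	H
θ	TH
ι	I
κ	K
λ	L
μ	M
ν	N
ξ	X
ο	O
π	P
ρ	R
σ	S
ς	S
τ	T
υ	U
φ	F
χ	C
ψ	PS
ω	O
Α	A
Β	B
Γ	G
Δ	D
Ε	E
Ζ	Z
Η	H
Θ	TH
Ι	I
Κ	K
Λ	L
Μ	M
Ν	N
Ξ	X
Ο	O
Π	P
Ρ	R
Σ	S
Τ	T
Υ	U
Φ	F
Χ	C
Ψ	PS
Ω	O
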