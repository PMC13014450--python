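# Secondary-structure element definitions (PDB residue numbering).
# Only ranges with published residue bounds are listed; users supply the rest.
# protein	name	chain	start	end
TmY	alpha3	A	62	72
TmY	alpha4	A	87	95
EcY	alpha3	A	65	74
EcY	alpha4	A	92	100
EcY	alpha5	A	113	127
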