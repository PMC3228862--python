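>AluY synthetic Alu-family consensus (311 bp); carries the documented AluY primer windows at consensus positions 66-86 (H) and 278-295 (T)
GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGA
TCACGGAGGTCAGGAGATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTA
AAAATACAAAAAATTAGCCGGGCGTGGTGGCGGGCGCCTGTAGTCCCAGCTACTCGGGAG
GCTGAGAAAAATACAAAAAGCAGGAGAATGGCGTGAACCCGGGAGGCGGAGCTTGCAGTG
AGCCGAGATCGCGCCACTGCACTCCAGCCTGGGCGACGAGCGAGACTCCGTCTCAAAAAA
AAAAAAAAAAA
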