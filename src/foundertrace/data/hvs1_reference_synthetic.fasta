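>HVS1_synthetic_reference positions 16051-16400 (synthetic stand-in, not the rCRS)
AACTCACCTACCACCCACACCTTAGGACTAGGGGCCTGGGTTAGGCGGCGTACGAACCAACGGCTCCGAC
TTGAACGTTACAAGCACTTTCAAGCTACCATCGACGGCGTTATTCGCCTAGTCATTGCTATGTCGTTAAA
GCTGACACACCATGCGTCCCCTTTCGCTTTAACATTGTATCGCAGGCAACACTTCCTGGTTCCCGGCTGG
AAACGTAACTAGGAGGTGAGCCAGCCTGTTAATTCTCCAAAAGTACATGGAGGATAACCACGCACCATGA
TGTTTCCACACCTCACAATCACAAAGTCGGGGTCTTTGGCATCCGACCGTGCCGTGAACTAACACTGTAA
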