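>CRP_promoter_synthetic synthetic stand-in, -550~+1 bp promoter window
ATCCTAGCCATTACTGAACAGTACTGCTTTTGCAAGGCATTCCATATAGCTTATATGCTATAGTAGAAAC
ATCCATGTCTATCAATATGGGGTCCCATTCTGCTGCTTACCCAACTCTTATCCATATAGGCCCCTGTGGA
TATGCTTTCAGTTAAAGTACTCTCAGACATAACCTGGTATCTATAGGAAGAAGTAATAAGAAATTTTTGA
GTAGTCTGCCCTAAACAGATCATAGTGTCACCTATGCATTGTAGTAAAGCTATACGATTGATATAGTTTT
TTCATTAATAATATGTAAGATCAGATACCTTCTTTGATACCGAGGAATGTTCATCATTGCATCATATCTA
GGAATTGTGGAAATGTTGAACAAAAGGGCCACAAGGGGGGCTATAACTGCTGAGGACCAGGAGTAGCTCT
ACCACAATGCATTGATAATTAACGATAAATGACACAGAGGGGGCTTTTTGGACAAGGCCCTAATTTAAGC
CAGCATGCGACCTGTATTGCTACCATAACTGTGGCACTTGCGTTGGCCACTCTTGATCTTA
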