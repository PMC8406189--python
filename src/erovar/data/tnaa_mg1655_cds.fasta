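>tnaA_MG1655 Escherichia coli K-12 MG1655 tnaA coding sequence (1416 bp)
ATGGAAAACTTTAAACATCTCCCTGAACCGTTCCGCATTCGTGTTATTGAGCCAGTAAAA
CGTACCACTCGCGCTTATCGTGAAGAGGCAATTATTAAAAGCGGTATGAACCCGTTCCTG
CTGGATAGCGAAGATGTTTTTATCGATTTACTGACCGACAGCGGCACCGGGGCGGTGACG
CAGAGCATGCAGGCTGCGATGATGCGCGGCGACGAAGCCTACAGCGGCAGCCGTAGCTAC
TATGCGTTAGCCGAGTCAGTGAAAAATATCTTCGGTTATCAATACACCATTCCGACTCAC
CAGGGCCGTGGCGCAGAGCAAATCTATATTCCGGTACTGATTAAAAAACGCGAGCAGGAA
AAAGGCCTCGATCGCAGCAAAATGGTGGCGTTCTCTAACTATTTCTTTGATACCACGCAG
GGCCATAGCCAGATCAACGGCTGTACCGTGCGTAACGTCTATATCAAAGAAGCCTTCGAT
ACGGGCGTGCGTTACGACTTTAAAGGCAACTTCGACCTCGAGGGATTAGAGCGCGGTATT
GAAGAAGTTGGTCCGAATAACGTGCCGTATATCGTTGCAACCATCACCAGTAACTCTGCA
GGTGGTCAGCCGGTTTCACTGGCAAACTTAAAAGCGATGTACAGCATCGCGAAGAAATAC
GATATTCCGGTGGTAATGGATTCCGCGCGCTTTGCTGAAAACGCCTATTTCATCAAGCAG
CGTGAAGCAGAATACAAAGACTGGACCATCGAGCAGATCACCCGCGAAACCTACAAATAT
GCCGATATGCTGGCGATGTCCGCCAAGAAAGATGCGATGGTGCCGATGGGCGGCCTGCTG
TGCATGAAAGACGACAGCTTCTTTGATGTGTACACCGAGTGCCGCACCCTTTGCGTGGTG
CAGGAAGGCTTCCCGACATATGGCGGCCTGGAAGGCGGCGCGATGGAGCGTCTGGCGGTA
GGTCTGTATGACGGCATGAATCTCGACTGGCTGGCTTATCGTATCGCGCAGGTACAGTAT
CTGGTCGATGGTCTGGAAGAGATTGGCGTTGTCTGCCAGCAGGCGGGCGGTCACGCGGCA
TTTGTTGATGCCGGTAAACTGTTGCCGCATATCCCGGCAGACCAGTTCCCGGCACAGGCG
CTGGCCTGTGAGCTGTATAAAGTCGCCGGTATCCGTGCGGTAGAAATTGGCTCTTTCCTG
TTAGGCCGCGATCCGAAAACCGGTAAACAACTGCCATGCCCGGCTGAACTGCTGCGTTTA
ACCATTCCGCGCGCAACATATACTCAAACACATATGGACTTCATTATTGAAGCCTTCAAA
CATGTGAAAGAGAACGCGGCGAATATTAAAGGATTAACCTTCACGTACGAACCGAAAGTA
TTGCGTCACTTCACCGCAAAACTCAAAGAAGTTTAA
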