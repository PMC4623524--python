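>18S_synthetic_consensus
TTGTTCCATGGTTACACTCGGGGTAGAAGCGAAAAGTGCGTTTGTAACCCCGGGACCGCTATCGGTGTCA
CCTCCCGAAATAACGTTTAGTGACCAGTGGAATTCAGCCACGGGAGCCAAGTTCGCCCGGTCTTCCGAGT
CCTGACAAGCGCCCCCCACCTATCTTTCCGAGATCGGAACTCGGAGTGAAATCATGTACCGAGCCCTAAT
CGCAGCTACTTGACAGCCCTTTACTGGTTATACCCAGCAAGGTCCTCGAGCCCACCCAGTACGATGAAGG
AAGAACATTATAGTAGCGCTTAAAATACATTTCGGGCCCGTCGTAGATACTATTATTAAGCAAGGCGAGT
CCGGCTCATCAGATGCCTATGGCTGCGCGTCCCGAGCGATCTGTTATTGGCAGACCATCATGTGTATCGG
GACAGCTGGAACCCCATACACGCGCATTACGATATGGGCTACTAGACCCCCTGGCTAGTCGCATTCGTAG
AATCTAGCCCTCCTGCTGCAGGGGATTCAGTAACGATGGGGGGGAACCAACTTCAACGGCCGCGAGTCCT
GGGCCTGCAGGCCAAGGACTCCGGTATGCCTCTGCATTGGTATATGGTTTACATTATGTTCATTATTAAG
CACAGCGCTGTCCGGCGAATCCCCGTGTAAGGCCATACATAGGATCAGCTCACCGTTTCCTCCCACTAAT
GGTTATCCGTGAAGCAACTAGGGTAGACCGCACCTCAGATTTGTCGAGTGCACACGACGATTCCACTACC
CGAGCGAATTAATGGCGCCGCACCACGACCCGGCTGAGCAGCTAATAGTGCTCGGCTAGCTCGCTGTGCA
GGGTGCCCCGACCGGCTGCGTGGCACGGGCTCGTCACCCCATGAACGAGGTAAATGAGCGTTCTCGCTTC
ACGGGACTCGAGCGGTTGACACGCCCGCCGACATAAACAGGTAAGCATGGCACTGGACATGAAATGTTAG
TGTGCCGCAGACAACAGCGACCCAATAAGTCGTCTAGAAACACGGACGTCTTCCACGACCAATTCGCCGC
CCATGTGGGGTACTCGCAGTCGTCACACACCAGGTGGGCGCCGTGCAAACCGCCGCTATCCGCTCTGTTA
CGCGGGACGACAAGGGGGTGGAACGCGGTGTATCGGTACCACTATAGGAAGCCCATAGACCGGGCAACGT
TCGTGAGCGG
>5.8S_synthetic_consensus
GACACCACGTACATATATAAGGTGAGCGATATGTGAGAAATCGCGTCGATCGCTAGAAAGGGTTAGAAAC
GGTCTCTGCGACCCCACGAAGCAAATGCGATATGCGTTACAAAGGCCGCGTAGGCTACGGCCTCTCGTCG
TCTTCGCTAGGAGGAGTCCT
>26S_synthetic_consensus
TATTGCTCGTGGCATGTATCCGGCTGTCCCATTAGCGGGCCACAGATAGCATCTCTCTTTGGGGGACTCA
ACTCGTGTACAACACCGAAATAGACTATCTCGAAACTGCCGAAAATACGCATGTGGCGGTCATCTGGGGG
AATTTCAGGCAGACGAAGGAGCCGCCTTTCGGAAAGCCTTTTGCCTCTGTACGTACGTAGCGAGCCTAAC
GTCGATGTCAAGATAGTATTCACTCTTGGTCTGCATAGCTAGGCTCGCAGAGAAGAGGGGTCTAGGCTGC
GCTGTGAGTTAGATGGTCCAAGCAGCATCCGTGGCAATTCTTGGGGCATCCCAGGAACCCCTCGAATGTA
TGCAAACCCCCAATCCGCATTTCTCACGCCGAAGTTAACATAGACGTAACGAGCACAGCTTGGACACCCG
ACTGGGTTCTGGCGGACGAAACCAAAGCAGGCTTCTGCTTGAGCGTGGCAACAAAGACTGTGTATCGGGT
ATGATCCACACAACATTCGGTTGAATGCGAACGGTGTGCGCGAGGGAAGCTCCCTGGCCGATTGTACTTA
AGCTGGGTTCCACTTTGCTCGAGTCCTCAAGGCCGCGCGGGAGCGCCATGCTCCCGATGTAGCGACACGC
CACTTTCGTCGGACTTGCGTTGTGGTCAACCCGTGACCCTCGTGGTTTGGAAAGCCTGATCAGCCAGACG
CATAGGAGCAGATGCGCCCGCCTGAAACTGGCCTGGGTGAGGTTTTTAACATCCATTTCCCCGTAGGAGA
TGGTAGGGAAAACGGGCATCGGGGCGATTTGTCTGTAACCCCGGCGGCGCGCGTGCTCCAAGTCGCCAGA
TCGCCTTTCACGCCTGCGGCCTGCTCGCATACTCATATGGATTACGCATGGAAGGCTCGCTGTATGTAAG
GTCAGTAAACCTGCGCATGACGTGGGCGTCCTGTGGGGCGACTCGCTAGGATCCCATTGACGGTGGATAG
TCCAACCGGGTTGGTACGCCACCGGTTAAGCCGGTAGCTTCAGGGCGGCTTGTCTAACACTGCACAGAGT
CATTTCAGAGCCGAGTTACTGGGATAGACGACTTACCGACAGCGGGTGTGTTTGCGCGCACCTTTCGTCC
GCTCATCGCTCTAGTTTTAAACCAGTACCTCGTAGGTACTCATCCATACCCATGCATGGATCCTAGCTGC
GGTCTTGCGCGGCCCGGGAACCAAGCGGTTGGATAACAGCCTATAGGTACGCCAGGCAGTATCACCAGCA
CTGTCGTACCTGTAGGAGGGGCGCGACAGTGTGACCAACT
>5S_synthetic_consensus
TCGTGCCTCTGCTTTGTTCGCTTACGCTAAAGAGTCATGGTTCGTCATGTTCCACACGATGAACGAAACG
CCTCGTTCTAACACCACCTCTAGCGATCGAGATCCACCTCCATTGTCCCT
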