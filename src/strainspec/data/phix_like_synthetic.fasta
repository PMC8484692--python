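>phix_like_synthetic synthetic decoy sequence (fixed, not a real genome)
CTGCATCGGCCTTTACATGATTCGACGATTGGTCCCCGCCGGACCAACATTTCGGCCTCTCATGGTATAC
TCAGTTAGTCACAACCGACACACAAGAACGTGCTGCCTAAAGCTGATTCAAGAACAAATTATAGTGACTG
ACGTTCCGTCATATTTTACTCCGGTGGAGTCGCACGCACCCGACTATGGCCCGAGATTAGTGGTACAAGG
TCTCAATCAAATACCGCGACGCGAAGGAGACTACTCTGGCTCTCAGCATCTTTGACTCGAGTATATCCAG
ACATAGGCACCCCGTTTATTGTATGATACGATACTACCGTATGACAACGCGTACAACCCAAGGTCGAACT
TCTACAGCATTACTGACTTGAATAACCATGCCAGTCGTCACGAGCTTTACGCCCAATGATTCCTGAACAT
CTAGTGACTACCATGGATAACGTGCTACTCTCCGGATGCTCACCACTTTACTTAAATTGAAGAGATGGTT
TGACCTGAGGTAAAGCGCTATCGGTCTCTTGAACTCTAAACTGGACATAACATAGATAGGAGCCCTTTAT
CTTGTACAGCTAGGTAAGACACTACGGTTCACTGAACGCCGGTGCCTCACGCCTGTACTAACCTCGCAAA
ACATCCCGCGTATCACACGTACCTACCCTGTCCATGCACTGCATCGCTAGCACTGGTCGTAGGCAAGCGT
CATCGGGCGCAATTAATCTACCCTCTTATCAGCCGTAACATGGGTTCAAAGACTTCGCGCGACACTGAGG
TGAATAAAGTCGTGTGGAAGCTTCCCATCGTACAACCTTTAATGTAAATGCACGGAGAACTAATATTGAG
GACAGGATGGTCTCGTGGTTCACTGATCTCAAGTCCGACGACGGAGCTGGTGGTACCCCGAGTCTTTTCT
GGTTATCGCTTGCCCGCAGTGAACCACTTGCTATTTAGCGCTCAGACGCCGTCCCATCGAACGAAGGCGA
GTTTCGAACGAGTCGATCGTTATACGCTAGCTAGAGCCGTCATCGCTATCCGGATTCATTTATGTAGCAT
CGTTACCACAAGGTATATTAGATGTGCTCCACAAATATCGAATGCTTCAATCCGCAGCGTGAGCGGGACT
TACGGAATCGCACAAAACTTGAGTTTCGTACCCGACCGGGCATCTGGGAGGATTGAATCCGTACCTGGGT
CGTTTCCGAGAATTTGCTTGCTCCACAGGACCCTAGATTTGATCAGCCTTGCGAGCAGTTTAAGAGATAA
ACCGAATGGCGGGGCAAGGCCATACTTCACACTCGGTGTCTGCCCCACGATATTCCTATGGTGCGCATGT
ATGCACAAAGTATTCTCCAGGGTCTCGCTGTTCGCGGAACCCTGGTACTTGCTAGAACGCAGGTCCACGG
ACTATGTCCGCGACTTTCATGGGAACGAACAAGATGTGGAAGCGCTGCCTTTGTGCTAGATTAACCTTAA
GACACGTGTACACGTGCGTAAGTTATTTGTAAGCATGGTAGCAAGTAAACCCAGCTTATACATCCTGGTC
ACATCGCGCTTACTATCCCAAACTCATTATACGACATCCGATTCAACTAGGCGGGATATAGCACAACAAA
CCTCAATCCGCCAGGATCTCCGGTACAGCCCTTAGGAAACCCCAGGATCTAAGAGCATAGCCATTTGCCT
CTGGATTTGGAGACGTCCCTGACATATTAGACAAAGTAGTGATGGAAGCTTTTGCCTCTGATCGCCAGCC
GCCAAATTCGTCCTGACCACAAATGCCCGTCCAAAGATCCCACCATAATCAAGTCTTACACAATTACGAG
GTGTTCCTATCTCTAGTATGAAGTCAGCCATTGCTCTAAGGACCGTTCACATTATTTCAAGTGACTAGGT
TCACCCAACATCAGAACATGCACTGATAACACGGTTCCACAGACGCACACTGGTCGCAGCACGATGAGCG
CGACCCACGCATACAGTCTCCTGCCTTAGGGCTTTAGTTTTTCGCACGCCTTATGGTACCCGCTTACCTG
CTCTTCTGAAGACGCCGGACTACATACTAAGAGAATCGGATAAATACCTTCTGTAAGTCCTGGCAGCCTT
AATCCGCATACAGGGTTCACCATATAGGCCTCCGCTTACAGAGTGCGTACTATGGATTGATACTTTCGAC
AGTACAGCAGGAGGCTACCCCATTACCTGCGGACGGCGACTGGTGCAAGTGACTATGCACGAGGGACTCA
CTTACCCACCTAATATTTTCCGTGGTAGATCCTGGGTCAAAACTTTCAAGGGAACTGACGTGGGCGTAAA
GGTTGCATATAGTCAATGCTCAGGATCTGGTCCAATTTAAAACAAGAGGCTTGGAGAACAACCTGGATTC
TCTCCAGGTAGGGCACGAACACACACCCCCCACACAACTGCCGAGGGCGCATTCACTCCGTTGGTTCAAT
CCGTCTAGTTAACTCAAAACCCGGGATGAAATATCCTCGCCTTGCTAGGTGATTTCGACCGAGTCGGCGT
ACGGGGTCTAAGGAAAGCTCAGTGGTCGCCTTCAAAGTGCCTAATAACGGCTGCCCAGGGCGTGTGAAGA
GCTATCGCGTGGGAACGCGGTGTCGTGCAATCTAAGTGTGACAAGATCGGAATTGCCACCAATCTCGATA
CTTGTGGGGGAGGACGGCGTCTTGCCCAGTCGATGAGACGAATTTACTGTAGGGTGTTTTTCTACTCCAC
TCTAAACGCGGACTGTAGGGTTCCCGCGTGCCTCCAGCTGCGATCATCAAATACTCGTCTATCCAACTTG
ATAAGTTTTTCCGCTGACCGATTGCGGAGACAGCGTTTTATCGTGCCCGTTTACTTTCAAACATAACTCC
CACCATCTGGCTGTCCACGATAAGGATGTGTTACGTCGGACGCGCTCTAGGCGTCATCTTAACCATCAGC
AGGCTGCCCGTGTATGGGGCGTAGAGTACCACTGGACCGCCCCGGATCTACTACTCTCGC
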