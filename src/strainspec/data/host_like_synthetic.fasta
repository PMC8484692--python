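>host_like_synthetic synthetic decoy sequence (fixed, not a real genome)
ACCCCTAGACCCCGCTTATTTCCTGGTCCGCCGAACCTAGTACGAGCCGAGGCCAGTCACATATAACAAT
CGTGTGGACGTATAAAAGGAGATAGGAGAAATCATCGGCGAACAGCCGTTTAACAAATACAAAGTGAGAA
CCACATACCGCGCGCCGTACCCCCGGGAGGGGCTCGCTGACATCCAGCAAATTTGCGAGTGTAGACCCTT
GAAAAATTGGTTTTAGGCAGTTGTGAATCCGACCGTACCCTATCCGGCACTGTCGCGCCCGCGTGACTTT
ATTTGATTCCTTTCTCCCTGCATACGAGGGAGTGATTAGGCCCTGCATGTAGATTTATCAAAAAGCACGA
AGCGCATAGTCATGGTGACAGTATTATTATTGACGCCCTATGCTTCTCCTGCCCTTCTTGGCAATGTGTA
TTAAACCGTATTTGCGAGTTCTCATAGAGCTGACGGTGTCTCTTATAGCGGAAATGGGAACTGGGAGTTT
GGCTCGACCTGCTCTTCGTAGAGCCTTGGGCCACGCAGAATAATCAACATCCCGGTAACATGTGCGTTCC
TGTCACCGATACATCTGAACGGGTAATTGGTCGAATTGTTGAGGGTGCTACAGATCCCAGAGATATTTGA
CATTTAATTTTGTCGTTACGGAAATCCAACCGGGAGCCAGAGACTAGCCCTGCAGACTATTCCATGAGGC
GGAAATTCTGCTTTTCCAGACCGTCCGCTACCAGGAACTGAAAGCTCCGTGTGGCCCCTCATTATGTCTC
CCTTAACCATCGAGCTGCGGTATCGGCCGCCATCCGGGGCTCGCACCATGTTGGCCAAGTGTATCGTCAA
ATCGCATAGTATATCCGGTTTGAACCGTGACTCGGTCACACCGCTGGACTATCGAGTACTGTACGAACAT
CGAATTAATGGCGTAGGTAAGCGCGACTGCCATAGGAACAGTATCGTGTCATGACTATCACGCTGTCAAG
GTTCGCAGACATGATGGGTGGGGGACTTGTTGTGGGAGAAAAAGCAGTGGTTGCAAGCTTCATTACATCA
TCTAGACCCCGAGATTTGTCAATGAGCCGTTCGAGTTTGGATTACCCCCCCGTACACGTACTTAAGGCAC
TAGATCAGTGCGCTAGACGTTGTCTGGGCAGTCTCGGGGCGGCCACCCGATAGGAAAATTGGGTGCATCG
TTTTATAATAGAGATATTAACGGTAATGGAGGTAGAAGACTGTTTCTGAATCAGGTCGTCAATTCGCACC
GCTCCAGCCAAATTCAGAATGAGTTTACGTAGGTCGAACCACTCACTCTTGTCCATTGATTAGTGGTGTC
ACTCGCTATGCCCGTAGATGCACCTGTTTATGCCTGTAGGACGCACGAAGGGCCGGCCCCTTACTATGCT
GAAGTAGGCACAAACGGGCGTGTAAGAGAGGTAGACTGTGCGAACTCTTCAGTGGAGGACCGGGCCTACA
TGCCAGGGCCATTCACACATGTGTTGGAGAATTCAAGCTGAAAGACGTCGGAGACGACCTTTGATGTCAG
CCTCCGATCTAAAGTGAGATCCACTATTAAGGTATCCATCACAAAACGGGAGACTTGCCTGACTTCAATG
TTATGAGTCCCACGGGACGGTCTCCTTCTACTCCATGGCGCCCTGATTCACTGCAAAATGCTATACTCCA
AATTAACTCCCGCATGGAAACAGCGCTCATGGGTGTTGCCTCCAACGCGCCCTTTTCCATGCCGCTAGAT
CAGTACTCTACGTAGCTATAACGTCCGCCGCGACCCCCGAGGAAACTGTGATCGGAAGCAGATTCCGTGG
CATAATTCTCCAAGCGGGCGCAAGTCGGAGTCTCAGTCGTGCTTTCAAATGAGAGACGACCCGCTGCCAA
GGCCTCAGCAATTGTATCGCTGAATGGGGCCCTGGCCAAATGAATTAATCGTTCGGTTTTGGGCGGGAGC
ACCAAAGCTAACGAGAGTCCTATTGTGAAATCCGGGGGTTTACCCCGAGCCGATGCTGTCAGTCGGGCGG
GATGTAGTTTAGATAGTCGAAGTTGCAATGCCTAGTTCCTAACCTGCCCCGTACGTAATTCTTACCGTTG
ACTATCCGAGAGCGATGTAGCTCCGTCGGGCTGGTTATGGATGACTTAAGATGAAATGGCCAACCTTGGA
TAATTCTTACCCCTTATATACTTGGTCCGGGTATGGAAAGGGCGCACCCTATTTCCCCATGGAGTGTAGC
AGGGGGACAATGATCCTAAGTAGTGTATACACCGCAAAGCGTTAACGGGGGCCGGATTACGGTGGCACTC
TACTTTGTCTATAATCTCCAGACCCGGGCGGTCGCGCAAGGCGGTGGCTTGAGCCATCATAATACGCAGG
CATCACACCCAAACACCTACCAACTAGGTGATCAAGAAGGGATTTCGCGTGAGTCTTCCTCGTGTCTCTA
AATGGCCCGGGGTCGAACGCACCCTTTCAGTGCTGTCCGATTACACCAACTACATTAGCCATTCCGCTCG
GCTCGACACTAAGCAAAAGGCCTTAATAAGCACCTCGCTAATCGCGTGAGAATCATAATCCTCCGGACAG
CTTTCTCTTCTCAGGTTAAGTCTGAGCAAGGCGGCTTGACTGTGTGAATCTAGCTCCCTATAGTCCATTC
TGAGTAAAATTCGCGTCCAAGGAGAACAACAAACAGGTAACAAATTGAGCCGTACGGAAAGCCTGTCGAC
CACAGTGATTTTTTCTACCGGTATCCTCGCACCTTAGTATCGTTCGTTGTTAGCGCCCCAGTTGTTCGAC
AACCAGACTTTGGGTTCTCCACGTTGCGGTTATAACATCAAGCTTATCTCTCTACCTACAGAGTCGTTTG
AAACCTTGTGCTTTGCTGGAGAGACTGAACTAAAGTAGGAGCGAGTCCAGATAAGGAACGTCTTTGACAG
CGAGATTAAAGCTTGAAACTGGGGAACGTTTTATAAGCTGGGATCGAGTTCCCGGCAAAACCCACTAGGG
TTGATACGCGGGAAAAGTTCCGCTATTCCGGCACACGGCCAGAATCTATAAAAACTTCCCTAGCGTTCTA
CCAGGGCTTGACCCTGATCAGACCACCCTAAGATCGTTCAGGTTTTCAACGTCCATGGGTCAGAAAGTAT
ACCACTCAGCCTAACATACTCGTTCCTGATCCCCAGACCCCGAGCACGACTACCCTCCGAAAGGCTAGTT
CCCTGGTTACTCCCGCCAACGGTGAAGTACCTAAAGGCGAACTCTTTGGTTGCACCTAGTAATTCTGTAG
AGGTGGAACCGCGGTTCGTCTAAGGTAGTGATAATTCAGTGTACCCATTTAGCCTTACAACTGCCTAACT
GGGCCCCATTATTGAGGCCTTCAGACCCGGGGGTAAGTTAACATCACCTTAAGCCGAACTGTTTAACGGA
ACTTCACCGCTCGTCTCCAAACTCCAGGGTATACGGATCTGGTTGCAGGAACAAGGCACCTTTGAATGTA
AAGCTCCGGCGGTTTTGTTAATTAGGTTCTCTCGCAAAATTAACCTACCAGATCAAGTACTTTCGACGGT
CCATTTTGGCTGGACTCGCGCCTTACAAGCCGTATCGGTGCTAGGTGACGAGAGGTAATCCGCGTATTCC
GCTAAGTTTGTATTTAATGGAGCATTACTGATCGGGGATGTGGCGGCGCTTTCCCAACATACCGAGGCTT
ATGTCTAACGTGTTGTTCTGGTGTTTTCATTCGAACGCGATCCAGAAGTTACCGCCCGATAACATGGACC
GCAGATTCTTTGAATTGTACGTTCAGTAGGGCGTAGCGGAGTGTCTAATCATTGATCCTCCTGATTGTAG
ACATCAGTGTGCAGTGAGGACGCAAAATGAGCTAAGTCTATCGCTAACGTACGTGTCTATAAACTAGCCG
GGACTCAGACATGCTGTGCTAGAGCTACTGACCAAGCCCAAGATTACGGGTGCGCCACTGCAGAGTAGAC
CAATCTGACA
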