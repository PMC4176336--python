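>L1_human_synthetic deterministic synthetic reference L1 element (coordinate stand-in; 1-based inclusive spans in sidecar)
CAGTACTCTAATTACGATTCTTCCGCGCGGTCTCCACGAAGTGCTTAGGCCATCCTAAGTTTTGCGATGA
CAGAACACTTTGCTGGACGACAGAGCTAAGGTCACTTTGTATTCAAGAAGTTATGCTGTATCCGTTGATA
GCTATCCGTGTTTTGGTCTCCACGGCCCGAATGTTTTAATGTGTAAAGCAGAATGACTCCCCGAGCCATG
GCCTGGGCAGAAGAACTGATGCAGGTGCCATTAATGTCTTCTCCGTCACGATCACAGGTGTAACCAAAGC
TAAGTTGGCCATTACGGTTTAGAAACGTGCATCAAACGTTAGGGGAAACCCATAATTGTAGTGCTTCATG
GCAGACTTACCGGTGGAGTGAGACAGTCTTCAGGCACTATCAAAATACCTGTAAGTAAGTGGAAATAGCA
GACATTATTTAGACCTAAAGGAGCCCGCCTTTTAGTCATGGTTACGAGTGATGGGTCGTCTGTCTTAAAA
GCAAGCAAATCATATGTGGTACTGGTGCTTTTGCAGGTCTCCGCATTAGAGTACCTGTATGGTTATTCCA
TTGGGACGGCCCCATTAATGACGTGTGCGTGACCACGAACTTGCCCGCACTTGGACCCCGGTCAGTTGAG
TTTGTCTGAACTTGCTGAAAAAAAGGCGTTATTCAGGCGGAGTCACCCTATAGGGTCAATACTTTTCACA
CAACAAAACACTTTTTAGGAGCAGCGACATGTTGTGCTGCGCAATTACACAAGAGCCCGATGCATAACCG
TATAAATGTAAGCTTAAACAAAGATGTCGCTTTTTTTCTGGAAGTACATGTATTTACTCGCCATAGAAAC
CCGATTAAACGTAGAGCACCCCGCACCTCCACCAGCGCAATCCCCTACATCCGGCGACCAACGAACTATG
CCTTCCACTCTGACCGAACGTCTACGTGGTCCTTTTGCGAAACACTTAAAGCGGTCAGCGCGAGCGGCAA
AGTTCGCAAGAAATTGTAGTAAGAGTGAACTAAAGTATGCCCTTGAGCAGGTAACCACAGTTGAAGTTTG
CCCTGTGATAAGTTACTGCACCAATAGGATAACCGCGCGCCCCGCCGTACTGCTGGGAGCTTCTGAGTAT
TTCCTAGCCTATCGGGCCTGCGGGCCGTGCCCTATCCCACCCCAGTGTAACAGAAATGGCCGCGTACGGT
ATAGTAGCTTTAGTAGCCCGAAGAGCCTCGCCGTGGAACGGGGCCGTATACGTCATGGTGGTCCGGATTC
TACCCGGGAACTGGGACTTCCTCTAAACGTTTTACAAGCTATTTCCGCTCCAAGCAAGGACCCCCGCAAT
TGGAAATACGACGGCTTATACCGGATCTACGGAGGGAAATCCACGGGATCGCTCACGCGTTTCACGTGCC
TAAAAGAAGTGCCTATATCATGTTCTCATACTAACGGTGAGCGTGTTATTTGTATGCTCGGACACAATTC
GCCGAGCGCTTTGCACAAAGTTAAGCGTAAGATGAGTGTACAACATTTCGCGCAACCGAATTATTGGGCC
GCGCTCACGGAGAAGATACCTACCCTAAGAGTATCGGGACCGGTAAGTCGCCCTAAAACGCCCGCATGCT
TCAGACGGACGCTTTGCACAGTATGTCCTGACCTTAGGTATTTCCGCTGTCTATGCTTTCGTCAACCGGA
GGTAGTTGCAGGGTTCCCATCAACTCGCTCACTGGAGAGGAAGGCCGAAATGTGTATATATCGTCGAGAG
CCATCTGAGGTATATTCCCTGCTAGGTCACTCCTCCTTTCACTGGCCCGCGCCGAGTGGATCATTCAAGC
CCACACAGCATGTCAAATCCAGACGCGTAGCACAATCTTCAACCTCTATTGGAGAGCGATTTTGCCTCTC
TAAACGGATAATCAAATGCGCAACATCCTAAGCCCCACTAACACATAAATCCCCGCTCATCCCGACCTAT
ACGGGCTCGAAGCCCAAATTGAAGGTCGTATGAAGCCCAGCTTCGCCGAACGGAAGTCCGACCGCATCAA
CCTCAGAACGCAGTGGTTCTCTAAAGGATTAATAGCGGGACGAATATTCGACTTACCGGAACCTATTGCT
ATAAGACCGGAGGCGGAAATCCGGTTGTATATGTCGGTGGTTGCAAGTCCCGTCGAACTATTACGCTGCG
GCCGCAGGCAGTTAATAATATCGGGGCCGATGCACTCCCAGAAGCCGTCACTCACCTCGTTCTGTCAACT
CGCGGTCATAGTTGCCAGGACGTCGCAGAGACTGTTCTGTATCAGCTGCTATCACCACGTTAGTGGTTGC
ACCCTAAGTGATGCTCCGGGAGGCTTCTTGACAAGCGGTCCTCGGACAACATCACCTGCTTCGACGCTAC
GAGAGTTAAGATGTCTTGGGAAAGAAACATTGCCGGAATCATTGGCTTGTTGGTACAAATGGCGAGACAA
CCCGATCGAGCTTTTGCCTTACGATAACTTCCTTACTTCATCGTCATTGATATACGTATACGATACTAGT
CTCTCTTCATTCTCTGATGTGAATGTGACGATAAGTAAGTTTGGGACGCCGGATCCACTCCCGGATTTAC
GGAACCAGGGTGATAGGACAAGAATAGCGCAGTGTGGAACTCACGTCCCAGTCACATGCTCTATAATCGT
CAAAAAATCATTCTGCCACATTCGTTGGACCTCAGGGTGTCCACACATCCCAAACGGGTTTGCGAACACG
ACATCATTTGGGATCGACCTAAGTAACTGCGATTTGTCGGGGAAAATGGTTGTCTCCCGTATGTGTTCAG
TCGCGGCGAGGACCTGTACGTCCCTGAGGGCCGTCCTCTTGACCGCAGTTCTGAAGCCAGACGACGGCTC
AATGGCCTCTATGCTGCTGTTATGCCAGCTTGTCATCGTTTTTTATAATATATGCTCATATCCTAAACAT
TACCTGGAACTGTGTATCAGATTACATCAACGCACTCAGCCACGATTGAGTACACCCTCTTTAGACACGG
TGATCAGCTATACAACATCCCGCTCAATGGTGCCGGAGATAGAAACCGCCCAGAAGCCCAGCGAGTATGC
TAATCTCGAAATCACTCTTAACCTCATGCTTTCTAGCCCAAGTTCAGTAGATAAAAAGAAACGTGCAACG
TCGTGCGCTGAGTTTCCTTGTCCGGACAACGCTCACTACGGGAAAATGTACACTGACTTCGGCCCTGGAA
AGGGACCTGGAGTCTGGTCGGGTAAAGGCGATGAATTGGATAGTTCAGTTACTATCGGTTGGCCGTGGGT
GTTAGAGACAAACGGGCCCGTTAGGCCCTTAACCTATAGCCTTTCGGTAATGTCGAGTAAGACTCCAACA
ACAGCCGTACCCTGGAAGGAGCTAAGTCTTCAAATTAACTTGATAGGAACAGCGATAAACCCCCACAGTA
TAGAGTTGTATGCGATTCTTCACTTAGTGAGGAAGGCCCAAGGTACTACCTTCTCGTCCGTTACCACTCG
TACTCGTGTTGCCACCCTGGGCAGTGTTGGTGATCCCATGGCAAGACTCATGAATACTACCAAGGTCGAC
GTAAGTCACCACCCATGCGGGGACGCGTTTGTAAGCCAAGGACCGAACTCTTCCTCCAATTGTCCTGCAT
ACTACACCTCATTGGCTAGCTACGCGGACTGGCCCTCACTGGCGAGTCACAGCCGAACTTCGAGCCACCA
TCAACTAGATAAGAGGAGGGGGGTTTGGCCATCTTCTCATTATAATTTGGATGGGCCCCTCAATAGACTA
TGGTTAGAAATAACGTGCACTTATCTCGCTCGGTTAGGTTCACACAGAATCGTCGTGCATTACAGGGATG
TCCCTAGAGGCAACGCATATAGCCATTCTACCCCCGTAACTGTAGTCAACGCAGGTTCGTCTCTTGCGTG
CTGCTACCCATCAGGGGACATCGTAAAGCGCTCGAGCGCTGTAAGAGCCGTACAGTACAACCGCATTACC
AGTTTGGACCGTCCTTTCCGAACTCGGTCTGTCGTTTATCGACCTCAAGGTATCTCATCCGACCAAAATT
TCTTTAGCCCACCCCACGGGGTCACTCTCTGTGCCAGGAAATCCGCAAGTAGGTACCACAGTAATTTCTG
TAAGAGCAGAGAATTGCGCATGATCGGCAACACTAATCCGTTTGTCCTTATAATTGGGCATTCCACAGTA
AATTCATTAAATACCCGTCGCCCGAGACAGGCTATTGTGCGCGAATCGATCGCAAACAATGGCAGTTTAG
AGAGTTTGCCTCTAAAACAGAATACACCGTCTATTCCACCCCTCGCCCGTACTAGGCCGGTGCCAAGTTG
TGCTGCCACATTCAGGACTTGGCTACCACTAGTATTTGTTATCAACAAGAGCAGCTTGAGCTGTACAAGA
TATGACCTGGACTCACCGTCAACAATTGGTCATTATAGTTCAATGTCTGTGATCGTGGACCATGACCACT
TGGGGGTTTTTAACGAAACATCTATCTACGTTCTCACTCGGGTTCCGTGCTTCTCCCCAAACGTGACGGT
TGATTTGGTAGAGACTCCTTCCAGAGAATGTTGGAGTTCGCTGATACATCACGGCGCACCATTAATGTTG
CTGCAGGCTGCGTATAAAAGTCGTTTCCGCCACATTATACTTTTTGATCACAATCAGGTCTCCGCGTACA
TGCTCAGCCGAGCGACTCAATGGAATTACGACGGATACATCGTGGTGCCTCCTCCGCTTACGTTGAACGC
TATGAAGAGGTCTTCGAAGGGGGGGTTCATATGCGGTTGGGCTTGGCCTGTTGCCCAACGCGTAAATAGC
CTGGTAACGGGTGTCTTAATAACCCTGCACAGCTACGATGGGACTTTGACAACCGCTGTCTTGCGCCCAT
ACGCCCGACCTGAGACCCTTCTACTAACTGAGCCGCTGAGTGCTCCGCAGCGTCGGACGCTATCTGGGTC
ATTTAATGTAAGGGCTTCCGTTGCACAGACCCTGATCATTCGACGTGCTGACTGGCTGGGCGTCTTAACG
CATGTCAATGTTGCGCCGGATGCGATGGCATCGTTCCTTGACAGCCTTGGCTACGTTATCGCGGGAGGGC
GGAGCCGTCGAGTAGGTCGATTCGCAAGGAACCCAATGGTTTTTAGAATCGAAATTAGCCCATTTCGACA
AGCGACCATCACAGTAAAGATTAAGATAACGTGGCCCATCATTGAAGCCATACTTGACTGCGTGACACTG
GCCACTCGCACAAAAGCTTATGAGAGACTGCCACGTCCACAACGGGGCGTAGGGGTTACGGGACTGGGCG
CTATCAGTATTTCTGCCCTCGCGCGGCCCGTCTATCTTCACGATCGACATAACTGCGGTTTCGCTGGGCA
ACGACGATCCATATCCCTCCTTAAGGCACCCAGAGGTCGATACAGTATTTCTTATAAGGGTCGAAATTTA
TTCCTGGGAGTCGAAAATTCCTTGGCATATGAGTCCCATTCTTCGTTTCCGGGAGCTGGACAGTCTGACG
CATATCCTCCTATAAAAGTCAGCTTATTCCTACCGAAAGGACCTGTATCACAGCAGGACGATCACACTAC
AAGGTTGCGGTGCCCGCCTTGTCTATCCCAGGGTGTTATTTACGGCGAGACGGGGAGGTTTCACCCTCTT
CATAAATACGGAGCCGGTATCTGGAAGTCGATGAACTATAGCTATGGGTCTGTGTCTTACTTGCGTCGAC
CACCCGTTCGCAGCGCGAGACGGGTATATTTTGACATTAAAATCCTAAAATACGAGGCACCAATTGCCCT
CTCATAACATCAGTGGGGAGATGCATACACTTGTTCACGGTCGTCAGGAATGTCTCGTAACGTTTATGGG
TATGTCATAGACTCCGTCTTATCGCATGAATGCTCTTATTCAACCACTCTAGCAAACGACAGTATTGTAA
ATGGTAGGTGGCCTCCAATGAAGGCGCTGTGGCTATATCAAACACTCATAGACATCTACGGAATGGCCAA
CCAGATCCCTTGCCAGATAAAAGCGTGACA
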