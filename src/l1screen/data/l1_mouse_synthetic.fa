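>L1_mouse_synthetic deterministic synthetic reference L1 element (coordinate stand-in; 1-based inclusive spans in sidecar)
CTTACTGCCATGGCGTTTCCGCAGTCCTGATAAGGTTAAAGTCGATGTTATAACTCTAGCTTCAGGTAAC
AGCAGGCGAGTCTCCACGTCGATTGTGTACCCCCAGCGATCTTTTCATACTTATAAGGAGCTAGCCATGG
ATTTACTGAGGCTGGTGGGTTTCTTCGGCCCGCCCAGACCTGCTGCGTCCGTATTCACCACTTGGAAGAA
AAGATTGCCCGGGCAACTTTACAGACGGAATCAAAATTGACTTATCTGGGTCGACAATTACTTACACGGC
TTTATCAGCGCTAGAGTAAGATTAATAGTGCGACGAGACCGAGATTTACTAGGGGGTACTAGAAAACGAG
CGCAGTCAGGATCTCATGCATGTTGGCATCGAACGCTTTTTTACCCCGGCGTGTAATGCCATGTACGCCT
GTAGTCTGCGTGGCCTGAGTATAAGAAAATTCGTATCACTTGCTTCAAACCGTCCCGCGAGTAATCTGTA
AGGTAAGTGCGTGCCTCGCCGTTCGTATTGCGCAGACCATAACCCTTTATGGCTTAATGCATTGAGTCGC
ACAACTGAAATTTTAACCGAAGTGCGTGTCCCAAAAATCTGTTGGGATAACCTAAAGCGGCCACCGATGA
GGCCGAAGCAGCCTGATTCCGTGAGCTTGTGGCTATAGAATCGGGGAGCACACTGGGTCTAGCCCCACCA
AAGTTATGCGACAGGGATTATGGTATGTGATTTGTCACTCTTCGCAGAGTCACCAATTTATGCATCTCCC
AGGGATACATGACCGATCGTACATGCAGTTCGAATAACCACGACCTCTCTAGAAGCCGGCACAAAAGGGC
AAAACGCGCTTTGGCCCCGGGTACTCGAGAGTCCTGCACGCCCTGAGGGATGGGCAAGGGGGCCACGCAG
CACTAGGAAGCTACATTATTGTACTCGGCCAACTATTATTTTGTCTGTAGCCGGATCCCCACGGTGAAGG
CACGTATAAGTGACACGCCTATATTAATGCGAGTTCTATCGCGTGTTTGCGTACACAGACAGTCGATCTA
GGCTCATTTGACGAGCCCAGCATATTGAGCCCTCGTACATGGAATCACGCTCACAGTACACTCCAATGAT
ACCTTTATTCAGAGTGGACAATTGTGGCTAGTCCCGTTAGCGGCTGCGGCGATCGCGGAGATGGTCAGAG
CCCCCTTTATCACTAGCAAAGAGTCCGTTTGGAGTCAAACTTCTTATCTGCTATCGAACAGCTAGGCATG
CTCCACTATGTCATATTATCTGTGTCCCCAGCCGGAATACGTTCTCTGGGACTGCCAATTTTATGAGTCG
TCTCGCTTAGAATCCGGAATCCTGGGCGACGTGTAATCGACGCGGCTCACTATTGTAATGGATGGATTAG
AGAGCCGAGTGCATAACACCTATGGGTTTGGAATTACAGCTATAAAGGGGTCGCACGCCCCATCTAACGA
ACGCAAACCGCACCGCAACGGTTAATTGTATGGACAGGCATCCCCCGCATTTACATAGTAATGACACCTT
TTGTTCATGTCAACATTGCACGTTTGTTACAATCGTGGTACAGGGGATTGCAGTTGGCCAGACTGAACAC
TCTAACAGTAGTACAACCGCGCATGACACCTACGAAGTATCGGTATGCGGCTATGTACGAATTAGCAGTT
CAACAACAAATCTAATGGCTCAGGAAGTGTCCCGCCGAAGGCAATCGCCTGGATGTTTATCGCCTCAAAC
TGGTGACTTCAGCTGTCAACGTGGGAATACTTCCTATACCGAACTCTCGACTCTGGCGGTTAATATCATG
GATTGCGTTAAGCAAGGGACGTTGGCGAACAGACCTAAACGTCCGTTGTCTCGTAGGGTCCGCGAACCTG
TAAGCGAATCGGTGCGTCCAGAACCCTCACGAACGGGGGCCGGCGAACCTTATGCTGTCTTGAACGAGAC
GCAGGTATTAAGCCCTTTGCAGCACATACCCGAGAACCCGCCCTCGGTTGAGTTAGACGCTCCTGAGCCA
GATCAAATTCAACCTCCCGGCTGTACACACACGCTCGTCTTCACTCGACTAGTAAATCATGCACTTAAAC
TAGAAGTTATTGTATACTGGTCGATACATAACCTTGTAATCAAAGATGAACTTGTCTCCGAAGGTGAATC
TATAACTAGGGCCTATACGGCGTTACGAAACATTATCATGAGCGCACCAATTGAGCAGTTAGGCTGGCGG
AGGTACTATGCACGCCGGCTAATCGCAGTCTCTCGTTTGGCTAGTGGAAGCATATACTCACCAGTTGATG
CCATTATGGCCACCAGTCCCAGCCCTAGACCGACTTATTCCACGCACGGGCGCCGACCCTTCCGGAACAG
AGGTTACGCACAGTCGTCGATAAGCGACCCAGTAAGGGTGAAGATTGCCACGTACAGGACCCTGAGAGTT
ATAGTTCGTATTTCGCATGAGAGGTTCGCCTCGAAACTCACGGCAATGACGCGCGAAGTTCTGTTTACTC
TTCGCTACCGCACTTGCGTTCTCTGGCATACGTCCACACTGAAACGCGCTGTAGGAGCAAATCTACATCT
CTATCGCAGGACGACTGATACAGGTAGCATCGTTAGCTATCATATTCTGGTTTCGCGAGGTGGTTTCCCC
CCTGTCTCGTCTACGAGACAGGCAGGCGTTAACCAGGGTTAATACTTAAGATTTACCGAATGGTTCGGGT
TGATGTTCGTACCTTTACGTTAACATCCCGCAATATCGAACTATTTCACGAATACGGGGGTGGACCGGAG
ATGTACCATGAGAACGCTGAAGATAAATTTCAATCTGTAAACCCTACACTATGTTCCCACAGTGTCATAG
TTCGTTACGATCGAACAAATACAGGGCATGCACCCCCCGTTCTGAATCGTATTGGTGAAGGTATGCGGTG
GTCCAGGAATAGCTTCGCAGCTATCCTCATTTTACGTTACTGTATCCGATTAAAATCTCCCGCGAGCGCG
CAGTTTAACACTCCTGTCGAGTCTAGGGGAGGCCTGGATAACCAGGAGATGAAACATAGCACATCTACAA
GGATTAAAACAAGGCTCCTATCTACAAATATAAATGTGCACTTTTCCCAGGTCTTGCCTCACGTGGCAGG
TATCCTTGATAGCAGGATTCGGCGCGTCGTCTCGCAAGACGAACGACCGCCTCCCCGACCGGAGAGCAAA
TTCATGCTCTCTACACGCATGCTTAGAAGAATTAACCGGTGTAATTCCTCTCGATACTGGCGTCGCGCCG
TTTCGATCTACGCACACCACACGGTGTCACAACATGCGAAACCGTTGGTGCGATGGGTATCCAAAGACGA
CCTGAAAAAGAATGTATCCGATAGGTTTTCGGCGAGAATCACTGACGCGAGTGATCGATATGGTCGGAAA
GTATCCTATATCGTTTGCGCTCCTATAGCAAAACGGGCACGTAACTGTCCAGTGCCTCACAACGAGACGG
GGTGTGCAATCGCGGATAATTCTACCTATCACCTGACCAGTCCCGCCCAATACCAATGGCCGCGTCAGTC
TACTGCGACCAGACACATTGCCCAATGCTTACATTACTTGGTAATACTGCTGTCAATAACACTTCATGTC
ACTCGCAGATATCAATGCATGGCGCAAAAGTCCACGGCTTCCCTGATCAAGCGTCTGTGGAGGGGTCTAT
CAGGAGGTCCGTTTGAGTGGGATACATCTGGCATAGCCCAATTCGATGAATTCGATAACTTAACTATATG
GTCGACAGCTGTTATTTTGTGCATCTTTCTCGCCGCCATTCGGTTCCTAAGGTATTCTATGTATCTGAGG
ATAGGTAGTAATCCGGATTATTGCACGGTTTCCTCTAGTACCGTCCCCGTTAGTTCCGTGATACTATATT
CTAAAATGAAGAATTGCGTGGTTAAAAAGAAACGTAAGTATCATGCTCCCAAACTACGCCTTGTCTCTGT
AAGACCTATACCGCAGATCTGGATATTAAAATATACTACATGTATTAAAATGTGCCATAAGAACACTCAT
ATGTGCAGGCTCAAATATCGGCATGGCTGTCGTATCGACGTAGACCTCCTAGAGCTCCACGTCTTGGGGA
GTGTCGCGTGGCTCCACGTGCTATGTGAGTCTCCAAATGCCTTTGAACTAACGAATCCGTCTGGTGCTGG
AGCTAGACTCACGTACGCGCGACAACAGGCCTGTGGAGAAATATGGGCACTGAGCTTGTGGGCATATCTA
CCAACTCAATGGAAGGCCCGGACCTTTTGTACCACCGAGGCTAAAGCTATTCTATGTAGCAGGGTTATTC
GTTCTATGGGGTCGACATCCTTACAGGGTAGTTCGTACGCCACGGAAATAATGCTGCAAAGTGCACCGCT
ATTTATATACACACCGCAATGTAGGTATCCGAGTAATGTCGAAAACGACTATACCGAACAAACCTCGGCG
TCGCTTTGCTGCATATTCAACGAGCACTTTCTACGGATCTCGACTGCGGTGTCTATGCGACACTTCCACG
GGATAAGCGACATCAAGGGTTCATTATGCAGAGCATGCGTCTCACAATCGGATACTCTCAACAACCGAGA
AAGACGAGCCAAAGCGAGGTCGATAATGTGTAGGCCGATTAAGTGCGAAGTATTGGCTAGTGGTATGAAT
TTTGTTGAACCCATGATTGAATCGGTACGACGGTCTCTTGCAAGTCTACAAGTTGAACAAGCTGTTAAGT
TAAGGAGGCCCACGAGCCTCCCTAGAGGAGCCGTCAGTCGTAGGGAGGCAGTAATCGGGAATCGCCTTAC
CATATTAGTGATAAAGTTACAACGGAGTCACGGCCGATGGTCATTCCTGTGGCCTGACGACCATATCAAC
AAATTACGGCATTCAAGGTTAGTGTCTAAAGAGGTATCTGTAGCTAGACTAAATCATGTTGGTGCTCTAA
TGTGCGTAAAGGCAACTTATGCTTTTCGACACGCACGGAGCGGACTTTTTAGTGTAAGGAGGCACCTAAA
TGCCTATTCCAGATCGGTACGGGTGTCAGTAGGCGGGACTCCCGATCTAAGGTTCAAAACATTCTGTTGT
TCTATGCAGGGCACCGGGTGGACAATCTGTGTCTTAATTCGGATGTTAGATTCCGTCATCTTCTGCCATC
TACCCAGATCCCATCTCACGACTAAACCCCTATATCGTCTCGAGGAGCTGCACATTTATGACGGGACGTC
GAGTTTGCCGACGCCCCTGGTGTGGTGGGTGCCATCGAGCGATCGTCTCAAAAGCTGGATCCAAGATGAA
GTCAGATCCTGTTTTCTTGACTTTAGTAAACACGCCGAAGTTGCACGCAGAAGTGCGTGTAGGCAACCTG
CTAGGGAGTTGTCACTTGCGGGTGAGGATTGTTATCGCGAGCTTAACGTCTCTGGTCCGGGGACAGCGAG
CGCGTTAATCAGAGCCAAGAATCGAAAGTTAAACTTGGAGCAAGTTTGTACTTTGGCTTCGGATATATAT
GGTATGGACCACGGCTCCGCAGCGGACTTGCCTGTTGATGTAGATTTTCTAAGAGTGGGGAGCTTGAGGA
TCGAGTGGTTCGAGACAAATAGTCGGGATCTAGCGGATAAGGCACATACATACAGCATATGGAGAGCTAC
CATTTCTTCGTCGCCTTGTGCGGAAGCGTACGTGTTGCGAGGGTTTATTGCCCAGTTCTTCGTCCGGATA
CTTTACCGGAAGTCAAGTAGGAGATTTGAGGACGGGCGTAAATTTTGGACTACCCGCTTGACAGCCTATA
TGTGGACAGGAGCGGAGTACCTTTATTTGAAGCTGCTGTCTATTAGCTTCACATCCACGCTGTGGCTGAG
CAAGATCAGCCGGGGAGCTACAAGCAGCACGGGTGATACTAGGCCCAGTAAAGACAGGCCGATCAGAGTG
GCTCTACTCCTGAGGTACGTCTTCCCGCTTCTGGTAAACCGAGTCGGGTACCCACGACACTGCGTTATAG
TCAAAGACGTATGCCATTCCTGCGTGCTTCGAGGATCGATCCATTTGGTTGTCATGGTGATAAATAATGC
ACCCACGGTGAAAACCTTCGACGTATTTCAGTGGCCTTATATGAGTACGACTGGTGAAACCCATAGGGCT
TTTAAGGCCTTGAAAAAGCGACGAGTCAGCCAACCCCAGCTCAAGTCTCTTCTACTGCAGGACTGGGTTA
GTACATGTGGAAGTGCCTCTACTTATGCTAGTATGCTAAAGGTCCACAGTTTCGCTACCTACGACCACAT
GATACGTGATTGCTACAGAAATATGCCAACTTCTGATCTTTTTTGCATTAGCCCGAGGGCTGCACTATCT
TCGACCGCATGCATGTGCCCTGCGCAGACCCCCTCACAGATATGGCTACGTAAGTGTACAGCTAAAGGGT
TCTGGCTTATAACTCAAATTTGGCTTACGCGCCTCCATCTACATAATAGTCACTTGTCAGCCCATCGGGA
TGATGGAGAATTTCATCTCCTAACAGGCAGAGAGCCTCAACTGTTCATCGTTATCGTCACACCTGGATCA
GATCATTGCGCCTGGGATCCAAGTTACGTCCATTCTGAGGGTCAAACATTTACAACTCATTAATTGTTTA
ACGCCTTCAGCAGTTTAACATGAGATGCGAACGGGTCTCATTTAGGTTTTGTGGGGTAGCTTTTTGGTAT
GGCCACGGGAGATCCTATAAAACTGTGGAATTGACCAGCGTTCGTGTACGGCTCTTCTGCTCTTAGACCA
GGAGGCTTCCCAGGCGCCTAGTTAGTGGAATCTTTCTAACGTCCCTGTCAGAGCCATATCACACTAGCAG
TGGGCATAAGCCTACCCTTTATTTAGTCGTGGCAACAGGACAGTTCTTACCCTACAAGCCCCAATACAGT
CGTTCTACTGACCAAATCCAGTAGACTTAAACCTGGAACGGTCCCGTCAAGTATGTCAGAACTTCCGTTC
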