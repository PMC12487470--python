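>SB01
TGTGAGTCTGAGAACTCTGACTGA
>SB02
CATCGTAGGCCATGTGACCACATT
>SB03
CCCCGTTACTGGGATAGCTGACGT
>SB04
GCGGGGACGTATGCCGAATCCTCC
>SB05
CGAAGTGACGAATCGCTGGTATTG
>SB06
GCTATGTGTGCTCTTACTCTCTTA
>SB07
TTGAGCATCGATCTTGCTAGGGCT
>SB08
TTCGGAATTTGAGTGAGGCGACTG
>SB09
GTACGATGAGTCCGAGCCGCATGG
>SB10
CGGTCCATTTCGCAAACCACTTAA
>SB11
CTGACTAAACGTAGACTGGTGGAC
>SB12
GCGTGATCATTCATGCAATTCCGG
>SB13
CAATTCGTTCAGGGAAGTCTTGAC
>SB14
AATGTACACGGCCCGACTCCGTAA
>SB15
CCAATGTGCAGGCCCTTTACGCTT
>SB16
CATCTCGCCCTCCCTGCCTCACGT
>SB17
GTAATGATGTTGTTATTAGCTTTG
>SB18
CTGAAGCGACAATGGAGGCTGTTT
>SB19
ACATAATACCGTATACTATGGACG
>SB20
TGGAGACAGATTACCAGGCCGGCG
>SB21
CTGTTACTGGAGCATGGGTACGGA
>SB22
CTGGGCCTCGACAATTTTCTGGAA
>SB23
TCGATGAATTATTTGGTACGGGGC
>SB24
GCTCGACGGCGTGGACATTGAGGA
>SB25
GCTACACACAGCCACCAATACAGG
>SB26
CCACGCGATTGGCCTTCTAGCACG
>SB27
CATAGCGACAGATTATTTAAATTA
>SB28
AATCGCCCATTGGCACTTAAATCA
>SB29
ACACAGCCACGAGGGAGTAGCGAG
>SB30
TATAAATGTCACTTGATCTACACC
>SB31
ACCGATGTAACCTGCGTATGGATG
>SB32
TCCGGGCGAGCGTGGTTTACATTT
>SB33
AGTGCAGCCTATGCGGGAAGTCAG
>SB34
TGCTGCTTGATACCAAGTGATGAG
>SB35
CATCATAGCCCAAGCGCTTATGCG
>SB36
CACTATAACGGTTCAACCACTTTG
>SB37
ATGTAGCTAGGTTGAACGTGGCAA
>SB38
TTAGGTGATGCCCCGGAAAGTTGA
>SB39
ATAGGGAAAACCGATTGCAGAGGT
>SB40
CGGCATGAGTCCGCGCTTCAACCG
>SB41
AGCTGCACCCACGTGCCACGGGTG
>SB42
TGTCGCTCTACCTGGATGGGATTC
>SB43
GATAACATTTGAAACTCTGCACAA
>SB44
CTTTCGGAAATAAGAGTAACGAGC
>SB45
GTGCAGATTAAAGTGCGCGCCCTC
>SB46
TTCCCAGGGTAACACAAGTGACTT
>SB47
TGCTCGAGACCCAAACTAGTATTG
>SB48
TATTATTGAGTGTTTTCTAACTGG
>SB49
ACTTAAGACCCCTTATTGTAATAA
>SB50
CTCACACAGGCTACTGGGTAAATC
>SB51
TGTATTCGCGGGCTCCCCATCTAG
>SB52
AGTATAAGCATTTCGACCAGGCGA
>SB53
AGTCACTCGTCCGCTGATCCGTGA
>SB54
GGTAGGCGAGAGAAGAATCTCGAA
>SB55
CAGCTCGATAGTCTAAAGGCTCAG
>SB56
GACTGACTAGTTTGCCGATTTTCT
>SB57
CTTTTCATCTGACTACCATTAGGA
>SB58
CTTAGGGTTTATATGTACTATAGT
>SB59
GTGTTTTCGTTTCAGGACCTCTTG
>SB60
ATCCGACCATTAATCATCGGTAGG
>SB61
TCCGCCATGAACAATAAGGAGTTC
>SB62
GCACCGGGAATTAGTGTGACTGAT
>SB63
GCGTAGTTTGGACTAGTTGGGGTA
>SB64
CCTTACTAGGTTTGAATGGTTTCA
>SB65
CGAGTGACTTTGCAAAGCGTACCC
>SB66
ATTTTATTACAATATGCCTAAACC
>SB67
CTTCTGCCGACGTTCTTAAAACCA
>SB68
GGTGCGGGGATGGCCTGTTCACCT
>SB69
CGTTAGTATTTCGGGGTATGTCCC
>SB70
CTAGGAGCAAGGTCCTATATAATA
>SB71
TTGGCGCAATCAGTTAGTCAACGC
>SB72
AAATTCTCAGGGGTTTAGGTGTGG
>SB73
AGTGGGCCACATATACATTCCGCC
>SB74
ATGCTCTAACATTGAAATCTCCTA
>SB75
GACGCTCCTAACGTACGTTACCCG
>SB76
CGAGAGTTCCCTCCGCCCGAAGAG
>SB77
GTGATGTGTAGCTATCCCGGCAAT
>SB78
ATCTACCAGTTCGGTGATAGACTC
>SB79
TGGGAGCCGCTAGTAAGAGAGTGG
>SB80
CTGATCACCCGAGCCGATGTACAT
>SB81
ACCGCTCGAGACACGGGTTTAGGA
>SB82
CTGTACAGGCGGAATCACGTTCGG
>SB83
CCGCGCCATCGTATCAGCCCTATA
>SB84
TCTATGCGGCGACACCCGACTAAC
>SB85
GACATAACCAGGCCGCGATCTGGC
>SB86
CGCTGCACGACACGTTCATGAGAT
>SB87
GCGGCCAAGACGGAAGGCTTTAAC
>SB88
ATGTTCGGCCGCCTTTTCAGTGGT
>SB89
CAACAACTGTTCTTTGCGCATAGA
>SB90
CGTAGAGAATAAAGTATACACATC
>SB91
GAGTAGCAAACACCCACGCGAATA
>SB92
CGACAGGAGCCACTAATCCTTGCG
>SB93
CTTGAACAGCGCCTCCAGTATCGA
>SB94
GTATCCCGTTCTTCCTCCGCCCTC
>SB95
TGAGGACGTTATCCTACTGGGTTT
>SB96
CTAAGTCTTTGCATGCACTACTCA
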