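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
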