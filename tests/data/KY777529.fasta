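>KY777529 Melitaea acentria holotype COI barcode (BOLD BPAL2191-13)
ACTTTATATTTTATCTTTGGAATTTGAGCAGGTATATTGGGAACTTCTTTAAGACTTTTAATTCGAACTGAATTAGGAA
ATCCAGGATCTTTAATTGGTGATGATCAAATTTATAATACTATTGTTACAGCTCATGCTTTTATTATAATTTTTTTTATAGT
TATACCTATTATAATTGGAGGATTTGGAAATTGATTAGTTCCTTTAATGTTAGGAGCCCCTGATATAGCATTCCCACGAATA
AATAATATAAGATTTTGATTGCTCCCCCCCTCATTAATCTTATTAATTTCTAGAAGAATTGTAGAAAATGGTGCAGGTACAG
GATGAACAGTTTACCCCCCACTTTCATCCAATATTGCTCATAGAGGATCATCTGTTGATTTAGCAATTTTTTCTCTTCATTT
AGCTGGAATTTCTTCAATTTTAGGGGCTATTAATTTTATTACCACTATTATTAACATACGCATTAATAATATATCATTCGAT
CAAATACCTTTATTTGTTTGAGCTGTAGGTATTACAGCTCTTTTATTATTATTATCTTTACCAGTTTTAGCAGGAGCAATTA
CAATACTTCTTACTGATCGAAATATTAATACTTCATTTTTTGACCCTGCTGGAGGAGGAGATCCTATTTTATACCAACATTTA
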