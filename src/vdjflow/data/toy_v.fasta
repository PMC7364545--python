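>IGHV1-1*01
ACTTTGATACATGGTTTTACCTTGACTCAGTCCCGTTCTGTGTTCGAAAAACTCCTACACTGCAACCTCAGGCCCGCCATTCTGAAGTACTCGCTAGGAACACAAACTACTCACCTCGATTTTTCAGACTATCATAAACAATATGAGTGCGCTCCGATCGAAGTTATCATCGCCACCTGGACGGCCTCCCTCACATCAGGTTGTGTCAGACTCAATTCGTCTTCATCGAATATGGCGTTAAAGGGCGCGCACAGTGCTAATATGTTGAGCAGTGTCGGATGTGCGAGA
>IGHV2-5*01
AGTCCGTCCTGCTCGAGCGAATATTTGAAGAGCTTTTTTAGTCGGCCAGTGATGTTTGCTAAGAGCCCGAGGGAGGCATTAGACTCATTTATCGTAAGCTGTAAAGTACGCACCTCCGGGTTGATATTGCTATCGACCACTCCTCCACGAAAGAGCTTCTTCCTCAAGCACCTCTTAACGAAGTATACCCTCCGTCTGTTAAGCAATCCGGGGCGCCGTCCCTCTTACGTTCACCGCTTGACGCAGCCGACTATGCCGACCGATAACATCCGCAATGTGTGTGCGAGA
>IGHV3-7*01
AGAGGCTATCGACTGCGGTGCCTCTTGACTACAGTGCGTTTACATGAACTCCCGGTTCCCCAACAACGTGAAATCCTTGGTCTTATGTGCCATTGTGAATTAGCACCGTCGATCTTGCCGCTGGGGAATGTCATGACACCCGGTGTTAGTCACACTGCGATGATGCGGACGATCTGTCTTCAGCTTACCAAACAGTACGAACAGAATAAAGTCGTGTCGGCAGCTGAACGTCACGACTGTCTTATAACCCTGGTTAGGACGGCAATCTTGCACCGCCTCTGTGCGAGA
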