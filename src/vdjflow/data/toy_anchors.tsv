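# gene	anchor (0-based codon start)
IGHV1-1*01	279
IGHV2-5*01	279
IGHV3-7*01	279
IGHJ4*01	6
IGHJ6*01	9
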