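>IGHD2-2*01
AGAGCTCTGCACCGAC
>IGHD3-10*01
CATATCCGACCGAAAGAC
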