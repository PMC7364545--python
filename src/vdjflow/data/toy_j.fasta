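>IGHJ4*01
CCGCGTTGGAAGAGGATCCCTAAGGTTACCCACGTTAATCCGCCCATT
>IGHJ6*01
TTGCCATCTTTCCAAGGAAGGCGCGGGAGGAAAGCAACTTGGCGTACA
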