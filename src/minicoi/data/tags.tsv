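name	sequence
T1	AGCACG
T2	ACGCAG
T3	ACTATC
T4	AGACGC
T5	ATCGAC
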