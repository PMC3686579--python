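name	sequence	orientation	three_prime_block
LCO1490	GGTCAACAAATCATAAAGATATTGG	forward	0
HCO2198	TAAACTTCAGGGTGACCAAAAAATCA	reverse	0
dgLCO1490	GGTCAACAAATCATAAAGAYATYGG	forward	0
dgHCO2198	TAAACTTCAGGGTGACCAAARAAYCA	reverse	0
jgLCO1490	TITCIACIAAYCAYAARGAYATTGG	forward	0
jgHCO2198	TAIACYTCIGGRTGICCRAARAAYCA	reverse	0
Uni-MinibarF1	CAAAATCATAATGAAGGCATGAGC	forward	0
Uni-MinibarR1	TCCACTAATCACAARGATATTGGTAC	reverse	0
mlCOIintF	GGWACWGGWTGAACWGTWTAYCCYCC	forward	0
mlCOIintR	GGRGGRTASACSGTTCASCCSGTSCC	reverse	0
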