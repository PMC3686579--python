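name	sequence	orientation	three_prime_block
NecSav_block	CAAAGAATCAGAATAGGTGTTGGTAAAGA	forward	1
MyrBer_block	CAAAGAATCAGAACAGGTGTTGATAAAGG	forward	1
SarMic_block	CAAAGAATCAGAATAGGTGTTGATAAAGA	forward	1
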