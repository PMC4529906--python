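Chemokine	na	PTPN6	IRAK3	FLT3	BAD	CD36
Cytokines relating to brain	na	CD36
Cytokines relating to cancer	na	CD28	FN1	ABL1	EGFR
Inflammation relating to CRC	na	DDIT3	FAS	IRF3
Inflammation relating to brain	na	CCR6	CD28	DDIT3	FAS	FCER1G	NGFR	PPARD
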