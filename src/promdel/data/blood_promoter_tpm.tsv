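promoter	patient	control1	control2
APC-1B	11.70	30.28	26.18
APC-1A	1.72	0.68	<0.1
ACTB	2526.07	2208.45	2742.55
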