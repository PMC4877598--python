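sim5	40000	40200	APC-1B	0	-
sim5	70000	70200	APC-1A	0	-
sim7	5000	5200	ACTB	0	+
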