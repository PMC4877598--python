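gene	patient	control1	control2
DKK1	0.57	0.68	0.61
MYC	31.31	59.99	46.75
CCND1	0.34	0.91	0.97
PPARD	44.38	40.37	40.54
AXIN2	4.36	7.14	7.55
LGR5	<0.10	<0.10	0.12
CD44	780.90	573.60	784.35
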