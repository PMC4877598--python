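gene	mutation	protein	rsid	consequence	db_status	af_dbsnp
APC	c.T1458C	p.Y486Y	rs2229992	synonymous	non-pathologic	0.45
APC	c.G1635A	p.A545A	rs351771	synonymous	non-pathologic	0.44
APC	c.G4479A	p.T1493T	rs41115	synonymous	non-pathologic	0.42
APC	c.G5034A	p.G1678G	rs42427	synonymous	non-pathologic	0.42
APC	c.T5268G	p.S1756S	rs866006	synonymous	non-pathologic	0.43
APC	c.T5465A	p.V1822D	rs459552	nonsynonymous	non-pathologic	0.76
APC	c.G5880A	p.P1960P	rs465899	synonymous	non-pathologic	0.43
MUTYH	c.G1014C	p.Q338H	rs3219489	nonsynonymous	uncharacterized	0.30
NTHL1	c.C901G	p.L301V	rs200420874	nonsynonymous	uncharacterized	0.0017
POLE	c.G1323A	p.P441P	rs116573514	synonymous	uncharacterized	0.014
POLE	c.C2935T	p.L979L	rs56081968	synonymous	uncharacterized	0.11
POLE	c.G3156A	p.T1052T	rs5744857	synonymous	uncharacterized	0.086
POLE	c.A4530G	p.A1510A	rs5744944	synonymous	uncharacterized	0.20
POLE	c.C5334T	p.A1778A	rs11146986	synonymous	uncharacterized	0.085
POLE	c.A6252G	p.S2084S	rs5745022	synonymous	uncharacterized	0.21
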