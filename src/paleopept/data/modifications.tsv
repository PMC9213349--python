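# paleopept modification table v1
# name	targets	delta_da
# targets: residue letters the modification may sit on; "nterm" allows
# attachment at position 0 (peptide N-terminus).
carbamidomethyl	C	57.02146
oxidation	M,P,W,Y,C,K	15.99491
dioxidation	M,W,Y	31.98983
trioxidation	C	47.98474
deamidation	N,Q	0.98402
pyro-glu-q	Q,nterm	-17.02655
pyro-glu-e	E,nterm	-18.01056
acetyl	K	42.01057
kynurenine	W	3.99491
iodination	Y	125.89664
diiodination	Y	251.79328
oxolactone	W	13.97926
dopaquinone	Y	13.97926
carboxylation	P,E,D	43.98983
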