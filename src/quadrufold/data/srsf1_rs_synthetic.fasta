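>SRSF1_RS_synthetic residues 199-248 of human SRSF1 (synthetic reconstruction; matches reported composition: RS1 199-225 has 10 Arg, region has 3 Tyr)
RSPSYGRSRSRSRSRSRSRSNSRSRSYSPRRSRGSPRYSPRHSRSRSRST
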