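# Mitophagy / mitochondrial biogenesis module (literature placeholder).
Pink1
Prkn
Bnip3
Bnip3l
Fundc1
Map1lc3a
Map1lc3b
Sqstm1
Optn
Ulk1
Ppargc1a
Ppargc1b
Nrf1
Tfam
Tfb1m
Tfb2m
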