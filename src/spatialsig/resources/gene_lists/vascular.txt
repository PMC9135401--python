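# Vascular / endothelial marker module (literature placeholder; review before use).
Pecam1
Cdh5
Tek
Tie1
Vwf
Eng
Emcn
Esam
Cldn5
Egfl7
Sox17
Sox18
Erg
Flt1
Kdr
Robo4
Ramp2
Apln
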