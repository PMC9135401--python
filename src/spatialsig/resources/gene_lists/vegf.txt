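# VEGF signaling module (KEGG-derived placeholder; review before use).
Vegfa
Vegfb
Vegfc
Figf
Flt1
Flt4
Kdr
Nrp1
Nrp2
Plcg1
Src
Shc2
Ptk2
Mapk1
Mapk3
Akt1
Hspb1
Nos3
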