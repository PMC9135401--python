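# BMP pathway module (KEGG-derived placeholder; review before use).
Bmp2
Bmp4
Bmp5
Bmp6
Bmp7
Bmpr1a
Bmpr1b
Bmpr2
Smad1
Smad5
Smad9
Id1
Id2
Id3
Msx1
Msx2
Chrdl1
Grem1
Nog
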