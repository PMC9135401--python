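# TGF-beta pathway module (KEGG-derived placeholder; review before use).
Tgfb1
Tgfb2
Tgfb3
Tgfbr1
Tgfbr2
Smad2
Smad3
Smad4
Smad7
Ltbp1
Thbs1
Serpine1
Skil
Ski
Tgfbi
Bambi
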