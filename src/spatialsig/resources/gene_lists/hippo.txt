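# Hippo pathway module (KEGG-derived placeholder; review before use).
Yap1
Wwtr1
Tead1
Tead2
Tead3
Tead4
Lats1
Lats2
Stk3
Stk4
Sav1
Mob1a
Mob1b
Nf2
Ctgf
Cyr61
Amotl1
Amotl2
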