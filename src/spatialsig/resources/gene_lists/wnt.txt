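# WNT pathway module (KEGG-derived placeholder; review before use).
Wnt3a
Wnt5a
Wnt10b
Fzd1
Fzd2
Fzd7
Lrp5
Lrp6
Ctnnb1
Tcf7
Tcf7l2
Lef1
Axin2
Dkk1
Dkk3
Sfrp1
Sfrp2
Wif1
Ccnd1
Myc
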