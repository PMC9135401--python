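# Glycolysis module (KEGG-derived placeholder; review before use).
Hk1
Hk2
Gpi1
Pfkl
Pfkm
Pfkp
Aldoa
Aldoc
Tpi1
Gapdh
Pgk1
Pgam1
Eno1
Eno2
Pkm
Ldha
Slc2a1
Slc16a3
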