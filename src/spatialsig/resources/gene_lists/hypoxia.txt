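# Hypoxia-response module (placeholder; review before use).
Hif1a
Epas1
Vegfa
Slc2a1
Pgk1
Ldha
Pdk1
Bnip3
Ddit4
Ak4
Egln1
Egln3
Car9
Adm
Ankrd37
P4ha1
P4ha2
Plod2
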