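# Fatty-acid metabolism module (KEGG-derived placeholder; review before use).
Cpt1a
Cpt2
Acadvl
Acadm
Acadl
Hadha
Hadhb
Acox1
Acsl1
Acsl3
Echs1
Eci1
Acaa2
Slc25a20
Fasn
Acaca
Scd1
Elovl6
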