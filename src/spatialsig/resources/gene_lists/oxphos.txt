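# Oxidative phosphorylation module (KEGG-derived placeholder; review before use).
Ndufa1
Ndufa4
Ndufb5
Ndufs1
Ndufs2
Ndufv1
Sdha
Sdhb
Uqcrc1
Uqcrc2
Uqcrfs1
Cyc1
Cox4i1
Cox5a
Cox6b1
Cox7a2
Atp5a1
Atp5b
Atp5o
Atp5j
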