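# Electron-transport-chain complexes module (KEGG-derived placeholder).
Ndufa9
Ndufb8
Ndufs3
Ndufs4
Sdha
Sdhc
Sdhd
Uqcrb
Uqcrh
Uqcr10
Cox6a1
Cox7b
Cox8a
Atp5c1
Atp5d
Atp5e
Atp5g1
Atp5h
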