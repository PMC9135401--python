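# TCA cycle module (KEGG-derived placeholder; review before use).
Cs
Aco2
Idh1
Idh2
Idh3a
Ogdh
Sucla2
Suclg1
Sdha
Sdhb
Fh1
Mdh1
Mdh2
Pdha1
Pdhb
Dlat
Dld
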