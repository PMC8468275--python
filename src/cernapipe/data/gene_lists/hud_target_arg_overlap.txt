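Abat
Aldco
Apoe
Atxn1
Bdnf
Camk2a
Col1a2
Creb1
Gria2
Cxcl12
Enpp2
Fn1
Gars
Gclc
Gfap
Gria2
Homer2
Kcnma1
Lamp1
Mpdz
Nfia
Pam
Pdia3
Ppp1r2
Pura
Rpl23a
Slc3a2
Sod2
Tra2a
Tubb2b
Ube2m
Vdac1
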