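Abat
Aldoc
Apod
Apoe
Atxn1
Bcl2l1
Bdnf
Btg3
Camk2a
Capzb
Cldn5
Cnp
Col1a2
Creb1
Cxcl12
Eno1
Enpp2
Erbb3
Fabp7
Fn1
Gadd45g
Gars
Gclc
Gfap
Gpm6b
Gria2
Homer2
Hspa1a
Hspa1b
Igfbp2
Jun
Kcnma1
Lamp1
Maob
Mapt
Mbp
Mobp
Mog
Mpdz
Nefl
Nfia
Nptxr
Nr4a3
Nsmaf
Ntrk2
Osbpl1a
Pam
Parp4
Pdia3
Pglyrp1
Ppp1r2
Ppp2r5c
Pura
Rad23b
Rpl23a
Scg2
Schip1
Sfpq
Slc3a2
Smpd2
Sod2
Tmed10
Tnfrsf9
Tra2a
Tubb2b
Ube2m
Vdac1
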