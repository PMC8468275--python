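Aebp2
Ahnak
Akap8
Akap9
Anxa2
Ap3b2
Aqp9
Arf6
Arhgef10
Arhgef10l
Asph
Auts2
Axin1
Bach1
Baz1b
Bcl9
Bdnf
Bicc1
Bicd1
Brdt
Btrc
Cab39l
Cables1
Camk2a
Cfdp1
Cnn3
Col25a1
Copa
Creb1
Csnk1g1
Cyhr1
D10Wsu102e
Ddx54
Denr
Dst
Ebna1bp2
Eif2s2
Eif4g1
Eif4g3
Elavl4
Elovl5
Elovl7
Eps15
Etfdh
Ewsr1
Fndc3a
Fus
Gak
Galnt7
Gba2
Gli3
Gpm6a
Gria2
Gsk3b
Hdac9
Hells
Hmgn1
Hook2
Igf1
Impad1
Iqgap1
Iqsec2
Irf2
Kcnn2
Kif5b
Lmnb1
Lrrc19
Luc7l2
Mapk8ip3
Mcm3
Mgrn1
Mitf
Mpdz
Mpp6
Mta3
Myo1d
Nasp
Nfia
Ophn1
Paip1
Pik3r1
Plcl1
Ppp1r2
Ppwd1
Prrx1
Rab8b
Rapgef3
Rapgef5
Rbm8a
Rbms3
Rbx1
Rdh12
Rere
Rhoc
Rps6ka3
Rrm1
Scn1a
Sdha
Skil
Slc25a30
Slc8a1
Ss18
Steap1
Tardbp
Tcf4
Tfdp2
Tmpo
Tnfaip2
Tom1l2
Top1
Tpm1
Yap1
Ybx1
Zbtb7a
Zkscan1
Zmat2
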