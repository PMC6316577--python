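name,coverage,topology,dE_c,dE_disp,dH_c,dG_c
SiO2-2FA1,HC,double_monomer,-57.6,-28.4,-50.1,-1.7
SiO2-2FA2,HC,double_monomer,-56.4,-20.4,-49.2,-6.3
SiO2-2FA3,HC,double_monomer,-67.3,-16.9,-59.9,-17.9
SiO2-Dim1,HC,dimer,-46.8,-24.2,-39.9,7.2
SiO2-Dim2,HC,dimer,-73.5,-24.1,-64.7,-12.0
SiO2-Dim3,HC,dimer,-51.7,-19.3,-43.4,2.3
SiO2-Dim4,HC,dimer,-58.5,-21.3,-49.4,-1.5
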