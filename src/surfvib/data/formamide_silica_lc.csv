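name,coverage,topology,dE_c,dE_disp,dH_c,dG_c
SiO2-FA1,LC,monomer,-69.9,-18.8,-62.8,-13.3
SiO2-FA2,LC,monomer,-44.0,-28.1,-38.1,8.6
SiO2-FA3,LC,monomer,-68.0,-26.4,-60.7,-9.6
SiO2-FA4,LC,monomer,-80.5,-27.4,-74.2,-21.3
SiO2-FA5,LC,monomer,-63.3,-15.6,-56.8,-19.3
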