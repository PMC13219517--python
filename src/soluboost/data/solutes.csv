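name,Tm_K,dHfus_kJ_mol,q_J_K_mol,r_J_K2_mol,hansen_MPa05
butyl paraben,340.5,26,77.2,0.490,21.5
fenoxycarb,326.3,26.98,106.5,0.0424,26.08
fenofibrate,352.05,33.5,124.3,0.5192,19.72
risperidone,442.4,43.9,158.1,0.5214,21.87
butamben,330,24.1,130.0,0.862,20.63
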