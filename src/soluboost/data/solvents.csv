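name,dielectric,bp_K
methanol,35.2,337.8
ethanol,24.8,351.2
1-propanol,20.5,370.4
2-propanol,17.4,355.6
1-butanol,15.7,390.7
acetone,19.5,329.4
ethyl acetate,5.4,350.8
toluene,2.2,383.2
acetonitrile,34.1,355.3
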