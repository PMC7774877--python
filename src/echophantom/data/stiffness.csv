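material,durometer_shore_a,youngs_modulus_kpa
Lay-fomm 40,4,128.5
Lay-fomm 60,16.5,584.8
Gel-Lay,17,1493.7
TangoPlus,29,609.5
Silicone-0050,5,96.5
Silicone-0020,2.5,17.8
Jehbco silicone,39,2350.0
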