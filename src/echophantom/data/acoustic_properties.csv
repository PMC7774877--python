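material,density_kg_m3,attenuation_db_cm,velocity_m_s,impedance_1e6,backscatter_db
Lay-fomm 40,1082,6.57,1468,1.59,-22.50
Lay-fomm 60,1041,5.95,1544,1.61,-20.41
Gel-Lay,1023,6.24,1581,1.62,-17.86
TangoPlus,1100,29.31,2039,2.24,-32.60
Silicone-0050,1363,4.62,1063,1.45,-18.22
Silicone-0020,1202,3.52,1038,1.25,-15.26
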