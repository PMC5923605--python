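name,primary_diameter_nm,density_g_cm3
NM-100,100.0,3.84
NM-101,6.5,3.84
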