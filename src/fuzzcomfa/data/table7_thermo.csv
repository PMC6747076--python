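path,group,frequency_cm1,delta_g,delta_e,energy_unit
Path 1,-CH3,35.02,-0.026,39.307,a.u.
Path 2,-H,39.97,-0.023,39.439,a.u.
Path 3,-C2H5,35.60,-0.023,40.617,a.u.
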