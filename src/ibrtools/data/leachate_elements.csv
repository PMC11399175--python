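element,mean_ug_per_L,sd_ug_per_L
Ag,0.77,0.439
Al,82.5,27.6
As,0.355,0.095
Au,0.137,0.154
Ba,542.0,42.7
Co,2.70,0.569
Cr,0.193,0.308
Cu,72.4,14.3
Fe,199.0,84.9
Ga,47.1,8.42
Ge,0.279,0.045
Li,323.0,86.1
Mo,1.74,0.253
Ni,1059.05,362.0
Pb,5.95,3.01
Sb,48.3,3.54
Sn,18.2,6.63
Y,0.053,0.022
Zn,253.0,35.8
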