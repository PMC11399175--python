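Al
Sb
As
Ba
Be
Bi
Cd
Cr
Co
Cu
Ga
Ge
Au
In
Fe
Pb
Li
Hg
Mo
Ni
Se
Ag
Sn
V
Y
Zn
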