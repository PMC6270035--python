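# Positive-mode adduct registry: name<TAB>multiplicity<TAB>delta formula<TAB>charge
# m/z = (multiplicity * neutral_mass + mass(delta)) / charge.
# Hydrogen-ATOM convention: the [M+H]+ delta is one H atom (1.0078250 Da),
# with no electron-mass correction — this is what reproduces TOF software
# "calculated" values for protonated molecules.
[M+H]+	1	H	1
[M+Na]+	1	Na	1
[M+K]+	1	K	1
[M+NH4]+	1	NH4	1
[2M+H]+	2	H	1
[2M+Na]+	2	Na	1
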