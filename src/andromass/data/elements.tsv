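# Monoisotopic (lightest-isotope) masses in Da, one "symbol<TAB>mass" pair per line.
# These fix the exact-mass convention of the whole package; edit with care.
C	12.000000000
H	1.0078250319
N	14.0030740052
O	15.9949146221
Na	22.98976928
K	38.96370649
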