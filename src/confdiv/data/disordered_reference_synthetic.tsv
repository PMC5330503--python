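# Synthetic stand-in for a disordered-protein amino-acid composition
# (DisProt-like: enriched in P/E/S/K/Q/G, depleted in W/C/F/Y/I/V).
# Illustrative default only; supply your own two-column table (aa, frequency)
# for real analyses.
A	0.0767
R	0.0562
N	0.0409
D	0.0593
C	0.0082
Q	0.0511
E	0.0922
G	0.0767
H	0.0204
I	0.0337
L	0.0665
K	0.0767
M	0.0184
F	0.0235
P	0.0869
S	0.0869
T	0.0562
W	0.0051
V	0.0460
Y	0.0184
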