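# Synthetic stand-in for an ordered/crystallizable amino-acid composition
# (PDB-Select-25-like). Illustrative default only.
A	0.0838
R	0.0494
N	0.0434
D	0.0585
C	0.0141
Q	0.0383
E	0.0626
G	0.0767
H	0.0232
I	0.0565
L	0.0890
K	0.0595
M	0.0212
F	0.0404
P	0.0464
S	0.0605
T	0.0565
W	0.0141
V	0.0706
Y	0.0353
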