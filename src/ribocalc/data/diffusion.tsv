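amino_acid	diffusion_coeff
A	8.3e-13
C	8.3e-13
D	8.3e-13
E	8.3e-13
F	8.3e-13
G	8.3e-13
H	8.3e-13
I	8.3e-13
K	8.3e-13
L	8.3e-13
M	8.3e-13
N	8.3e-13
P	8.3e-13
Q	8.3e-13
R	8.3e-13
S	8.3e-13
T	8.3e-13
V	8.3e-13
W	8.3e-13
Y	8.3e-13
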