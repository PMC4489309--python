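residue,basicity,hydrophobicity,helicity,isoelectric
A,206.4,1.8,1.42,6.00
C,206.2,2.5,0.70,5.07
D,208.6,-3.5,1.01,2.77
E,215.6,-3.5,1.51,3.22
F,212.1,2.8,1.13,5.48
G,202.7,-0.4,0.57,5.97
H,223.7,-3.2,1.00,7.59
I,210.8,4.5,1.08,6.02
K,221.8,-3.9,1.16,9.74
L,209.6,3.8,1.21,5.98
M,213.3,1.9,1.45,5.74
N,212.8,-3.5,0.67,5.41
P,214.4,-1.6,0.57,6.30
Q,214.2,-3.5,1.11,5.65
R,237.0,-4.5,0.98,10.76
S,207.6,-0.8,0.77,5.68
T,211.7,-0.7,0.83,5.60
V,208.7,4.2,1.06,5.96
W,216.1,-0.9,1.08,5.89
Y,213.1,-1.3,0.69,5.66
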