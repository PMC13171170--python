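# PAM120: PAM 120 substitution matrix, scale ln(2)/2
# Restricted to the 20 canonical amino acids.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A   3  -3  -1   0  -3  -1   0   1  -3  -1  -3  -2  -2  -4   1   1   1  -7  -4   0
R  -3   6  -1  -3  -4   1  -3  -4   1  -2  -4   2  -1  -5  -1  -1  -2   1  -5  -3
N  -1  -1   4   2  -5   0   1   0   2  -2  -4   1  -3  -4  -2   1   0  -4  -2  -3
D   0  -3   2   5  -7   1   3   0   0  -3  -5  -1  -4  -7  -3   0  -1  -8  -5  -3
C  -3  -4  -5  -7   9  -7  -7  -4  -4  -3  -7  -7  -6  -6  -4   0  -3  -8  -1  -3
Q  -1   1   0   1  -7   6   2  -3   3  -3  -2   0  -1  -6   0  -2  -2  -6  -5  -3
E   0  -3   1   3  -7   2   5  -1  -1  -3  -4  -1  -3  -7  -2  -1  -2  -8  -5  -3
G   1  -4   0   0  -4  -3  -1   5  -4  -4  -5  -3  -4  -5  -2   1  -1  -8  -6  -2
H  -3   1   2   0  -4   3  -1  -4   7  -4  -3  -2  -4  -3  -1  -2  -3  -3  -1  -3
I  -1  -2  -2  -3  -3  -3  -3  -4  -4   6   1  -3   1   0  -3  -2   0  -6  -2   3
L  -3  -4  -4  -5  -7  -2  -4  -5  -3   1   5  -4   3   0  -3  -4  -3  -3  -2   1
K  -2   2   1  -1  -7   0  -1  -3  -2  -3  -4   5   0  -7  -2  -1  -1  -5  -5  -4
M  -2  -1  -3  -4  -6  -1  -3  -4  -4   1   3   0   8  -1  -3  -2  -1  -6  -4   1
F  -4  -5  -4  -7  -6  -6  -7  -5  -3   0   0  -7  -1   8  -5  -3  -4  -1   4  -3
P   1  -1  -2  -3  -4   0  -2  -2  -1  -3  -3  -2  -3  -5   6   1  -1  -7  -6  -2
S   1  -1   1   0   0  -2  -1   1  -2  -2  -4  -1  -2  -3   1   3   2  -2  -3  -2
T   1  -2   0  -1  -3  -2  -2  -1  -3   0  -3  -1  -1  -4  -1   2   4  -6  -3   0
W  -7   1  -4  -8  -8  -6  -8  -8  -3  -6  -3  -5  -6  -1  -7  -2  -6  12  -2  -8
Y  -4  -5  -2  -5  -1  -5  -5  -6  -1  -2  -2  -5  -4   4  -6  -3  -3  -2   8  -3
V   0  -3  -3  -3  -3  -3  -3  -2  -3   3   1  -4   1  -3  -2  -2   0  -8  -3   5
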