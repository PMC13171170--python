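# BLOSUM80: BLOSUM clustered scoring matrix, 1/2 bit units, 80% clustering
# Restricted to the 20 canonical amino acids.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A   5  -2  -2  -2  -1  -1  -1   0  -2  -2  -2  -1  -1  -3  -1   1   0  -3  -2   0
R  -2   6  -1  -2  -4   1  -1  -3   0  -3  -3   2  -2  -4  -2  -1  -1  -4  -3  -3
N  -2  -1   6   1  -3   0  -1  -1   0  -4  -4   0  -3  -4  -3   0   0  -4  -3  -4
D  -2  -2   1   6  -4  -1   1  -2  -2  -4  -5  -1  -4  -4  -2  -1  -1  -6  -4  -4
C  -1  -4  -3  -4   9  -4  -5  -4  -4  -2  -2  -4  -2  -3  -4  -2  -1  -3  -3  -1
Q  -1   1   0  -1  -4   6   2  -2   1  -3  -3   1   0  -4  -2   0  -1  -3  -2  -3
E  -1  -1  -1   1  -5   2   6  -3   0  -4  -4   1  -2  -4  -2   0  -1  -4  -3  -3
G   0  -3  -1  -2  -4  -2  -3   6  -3  -5  -4  -2  -4  -4  -3  -1  -2  -4  -4  -4
H  -2   0   0  -2  -4   1   0  -3   8  -4  -3  -1  -2  -2  -3  -1  -2  -3   2  -4
I  -2  -3  -4  -4  -2  -3  -4  -5  -4   5   1  -3   1  -1  -4  -3  -1  -3  -2   3
L  -2  -3  -4  -5  -2  -3  -4  -4  -3   1   4  -3   2   0  -3  -3  -2  -2  -2   1
K  -1   2   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1  -1  -1  -4  -3  -3
M  -1  -2  -3  -4  -2   0  -2  -4  -2   1   2  -2   6   0  -3  -2  -1  -2  -2   1
F  -3  -4  -4  -4  -3  -4  -4  -4  -2  -1   0  -4   0   6  -4  -3  -2   0   3  -1
P  -1  -2  -3  -2  -4  -2  -2  -3  -3  -4  -3  -1  -3  -4   8  -1  -2  -5  -4  -3
S   1  -1   0  -1  -2   0   0  -1  -1  -3  -3  -1  -2  -3  -1   5   1  -4  -2  -2
T   0  -1   0  -1  -1  -1  -1  -2  -2  -1  -2  -1  -1  -2  -2   1   5  -4  -2   0
W  -3  -4  -4  -6  -3  -3  -4  -4  -3  -3  -2  -4  -2   0  -5  -4  -4  11   2  -3
Y  -2  -3  -3  -4  -3  -2  -3  -4   2  -2  -2  -3  -2   3  -4  -2  -2   2   7  -2
V   0  -3  -4  -4  -1  -3  -3  -4  -4   3   1  -3   1  -1  -3  -2   0  -3  -2   4
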