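# BLOSUM95 amino-acid substitution scores, 20 standard residues, in 1/2 bit units.
# Derived from the published BLOSUM series (Henikoff & Henikoff 1992, BLOCKS database).
# SYNTHETIC stand-in: the published BLOSUM95 table is not bundled;
# this matrix is the elementwise mean of BLOSUM90 and BLOSUM100 in
# bit units, rescaled to half-bit units and rounded.
    A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
A   5  -1  -3  -2  -3   0  -2  -2  -1  -2  -2  -2  -1  -1  -2   1   0  -1  -4  -3
C  -1   9  -5  -6  -3  -4  -5  -2  -5  -3  -2  -4  -5  -4  -5  -2  -2  -2  -4  -4
D  -3  -5   7   1  -5  -2  -2  -5  -2  -5  -5   1  -3  -1  -3  -1  -2  -5  -6  -4
E  -2  -6   1   6  -5  -4  -1  -4   0  -4  -3  -1  -2   2  -1  -1  -2  -3  -5  -4
F  -3  -3  -5  -5   7  -5  -2  -1  -4   0  -1  -4  -4  -4  -4  -3  -3  -2   0   3
G   0  -4  -2  -4  -5   6  -4  -6  -3  -5  -4  -1  -4  -3  -4  -1  -3  -5  -4  -5
H  -2  -5  -2  -1  -2  -4   8  -4  -2  -4  -3   0  -3   1   0  -2  -2  -4  -3   1
I  -2  -2  -5  -4  -1  -6  -4   5  -4   1   1  -4  -4  -4  -4  -3  -2   3  -4  -2
K  -1  -5  -2   0  -4  -3  -2  -4   6  -4  -2   0  -2   1   2  -1  -2  -3  -5  -3
L  -2  -3  -5  -4   0  -5  -4   1  -4   5   2  -4  -4  -3  -4  -4  -2   0  -3  -2
M  -2  -2  -5  -3  -1  -4  -3   1  -2   2   8  -3  -3  -1  -2  -2  -1   0  -2  -3
N  -2  -4   1  -1  -4  -1   0  -4   0  -4  -3   7  -3   0  -1   0   0  -4  -5  -3
P  -1  -5  -3  -2  -4  -4  -3  -4  -2  -4  -3  -3   8  -2  -3  -2  -2  -4  -5  -4
Q  -1  -4  -1   2  -4  -3   1  -4   1  -3  -1   0  -2   7   1  -1  -2  -3  -3  -3
R  -2  -5  -3  -1  -4  -4   0  -4   2  -4  -2  -1  -3   1   6  -2  -2  -4  -4  -3
S   1  -2  -1  -1  -3  -1  -2  -3  -1  -4  -2   0  -2  -1  -2   6   1  -2  -4  -3
T   0  -2  -2  -2  -3  -3  -2  -2  -2  -2  -1   0  -2  -2  -2   1   6  -1  -4  -3
V  -1  -2  -5  -3  -2  -5  -4   3  -3   0   0  -4  -4  -3  -4  -2  -1   5  -3  -3
W  -4  -4  -6  -5   0  -4  -3  -4  -5  -3  -2  -5  -5  -3  -4  -4  -4  -3  11   2
Y  -3  -4  -4  -4   3  -5   1  -2  -3  -2  -3  -3  -4  -3  -3  -3  -3  -3   2   8
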