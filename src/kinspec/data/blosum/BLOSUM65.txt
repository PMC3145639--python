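# BLOSUM65 amino-acid substitution scores, 20 standard residues, in 1/2 bit units.
# Derived from the published BLOSUM series (Henikoff & Henikoff 1992, BLOCKS database).
    A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
A   4   0  -2  -1  -2   0  -2  -1  -1  -2  -1  -2  -1  -1  -1   1   0   0  -3  -2
C   0   9  -4  -4  -2  -3  -3  -1  -3  -1  -2  -3  -3  -3  -4  -1  -1  -1  -2  -2
D  -2  -4   6   2  -4  -1  -1  -3  -1  -4  -3   1  -2   0  -2   0  -1  -3  -5  -3
E  -1  -4   2   5  -3  -2   0  -3   1  -3  -2   0  -1   2   0   0  -1  -3  -3  -2
F  -2  -2  -4  -3   6  -3  -1   0  -3   0   0  -3  -4  -3  -3  -2  -2  -1   1   3
G   0  -3  -1  -2  -3   6  -2  -4  -2  -4  -3  -1  -2  -2  -2   0  -2  -3  -3  -3
H  -2  -3  -1   0  -1  -2   8  -3  -1  -3  -2   1  -2   1   0  -1  -2  -3  -2   2
I  -1  -1  -3  -3   0  -4  -3   4  -3   2   1  -3  -3  -3  -3  -2  -1   3  -2  -1
K  -1  -3  -1   1  -3  -2  -1  -3   5  -3  -2   0  -1   1   2   0  -1  -2  -3  -2
L  -2  -1  -4  -3   0  -4  -3   2  -3   4   2  -4  -3  -2  -2  -3  -1   1  -2  -1
M  -1  -2  -3  -2   0  -3  -2   1  -2   2   6  -2  -3   0  -2  -2  -1   1  -2  -1
N  -2  -3   1   0  -3  -1   1  -3   0  -4  -2   6  -2   0   0   1   0  -3  -4  -2
P  -1  -3  -2  -1  -4  -2  -2  -3  -1  -3  -3  -2   8  -1  -2  -1  -1  -2  -4  -3
Q  -1  -3   0   2  -3  -2   1  -3   1  -2   0   0  -1   6   1   0  -1  -2  -2  -2
R  -1  -4  -2   0  -3  -2   0  -3   2  -2  -2   0  -2   1   6  -1  -1  -3  -3  -2
S   1  -1   0   0  -2   0  -1  -2   0  -3  -2   1  -1   0  -1   4   1  -2  -3  -2
T   0  -1  -1  -1  -2  -2  -2  -1  -1  -1  -1   0  -1  -1  -1   1   5   0  -3  -2
V   0  -1  -3  -3  -1  -3  -3   3  -2   1   1  -3  -2  -2  -3  -2   0   4  -3  -1
W  -3  -2  -5  -3   1  -3  -2  -2  -3  -2  -2  -4  -4  -2  -3  -3  -3  -3  10   2
Y  -2  -2  -3  -2   3  -3   2  -1  -2  -1  -1  -2  -3  -2  -2  -2  -2  -1   2   7
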