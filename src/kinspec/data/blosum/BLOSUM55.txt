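# BLOSUM55 amino-acid substitution scores, 20 standard residues, in 1/3 bit units.
# Derived from the published BLOSUM series (Henikoff & Henikoff 1992, BLOCKS database).
    A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
A   5   0  -2  -1  -3   0  -2  -2  -1  -2  -1  -2  -1  -1  -2   2   0   0  -4  -2
C   0  13  -4  -4  -3  -3  -4  -2  -4  -2  -2  -3  -3  -4  -4  -1  -1  -1  -4  -3
D  -2  -4   8   2  -5  -2  -1  -4  -1  -5  -4   2  -2   0  -2   0  -1  -4  -5  -3
E  -1  -4   2   7  -4  -3  -1  -4   1  -4  -3   0  -1   2   0   0  -1  -3  -3  -2
F  -3  -3  -5  -4   9  -4  -1   0  -4   1   0  -4  -5  -4  -3  -3  -3  -1   2   4
G   0  -3  -2  -3  -4   8  -2  -5  -2  -5  -3   0  -3  -2  -3   0  -2  -4  -3  -4
H  -2  -4  -1  -1  -1  -2  11  -4   0  -3  -2   1  -3   1   0  -1  -2  -4  -3   2
I  -2  -2  -4  -4   0  -5  -4   6  -4   2   2  -4  -3  -4  -4  -3  -1   4  -3  -1
K  -1  -4  -1   1  -4  -2   0  -4   6  -3  -2   0  -1   2   3   0  -1  -3  -4  -2
L  -2  -2  -5  -4   1  -5  -3   2  -3   6   3  -4  -4  -3  -3  -3  -2   1  -3  -1
M  -1  -2  -4  -3   0  -3  -2   2  -2   3   8  -3  -3   0  -2  -2  -1   1  -2  -1
N  -2  -3   2   0  -4   0   1  -4   0  -4  -3   8  -2   0  -1   1   0  -4  -5  -2
P  -1  -3  -2  -1  -5  -3  -3  -3  -1  -4  -3  -2  10  -1  -3  -1  -1  -3  -5  -4
Q  -1  -4   0   2  -4  -2   1  -4   2  -3   0   0  -1   7   1   0  -1  -3  -2  -1
R  -2  -4  -2   0  -3  -3   0  -4   3  -3  -2  -1  -3   1   8  -1  -1  -3  -3  -2
S   2  -1   0   0  -3   0  -1  -3   0  -3  -2   1  -1   0  -1   5   2  -2  -4  -2
T   0  -1  -1  -1  -3  -2  -2  -1  -1  -2  -1   0  -1  -1  -1   2   6   0  -3  -2
V   0  -1  -4  -3  -1  -4  -4   4  -3   1   1  -4  -3  -3  -3  -2   0   5  -4  -2
W  -4  -4  -5  -3   2  -3  -3  -3  -4  -3  -2  -5  -5  -2  -3  -4  -3  -4  15   3
Y  -2  -3  -3  -2   4  -4   2  -1  -2  -1  -1  -2  -4  -1  -2  -2  -2  -2   3   9
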