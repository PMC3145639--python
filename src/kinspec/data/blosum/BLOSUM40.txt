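# BLOSUM40 amino-acid substitution scores, 20 standard residues, in 1/4 bit units.
# Derived from the published BLOSUM series (Henikoff & Henikoff 1992, BLOCKS database).
    A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
A   5  -2  -1  -1  -3   1  -2  -1  -1  -2  -1  -1  -2   0  -2   1   0   0  -3  -2
C  -2  16  -2  -2  -2  -3  -4  -4  -3  -2  -3  -2  -5  -4  -3  -1  -1  -2  -6  -4
D  -1  -2   9   2  -4  -2   0  -4   0  -3  -3   2  -2  -1  -1   0  -1  -3  -5  -3
E  -1  -2   2   7  -3  -3   0  -4   1  -2  -2  -1   0   2  -1   0  -1  -3  -2  -2
F  -3  -2  -4  -3   9  -3  -2   1  -3   2   0  -3  -4  -4  -2  -2  -1   0   1   4
G   1  -3  -2  -3  -3   8  -2  -4  -2  -4  -2   0  -1  -2  -3   0  -2  -4  -2  -3
H  -2  -4   0   0  -2  -2  13  -3  -1  -2   1   1  -2   0   0  -1  -2  -4  -5   2
I  -1  -4  -4  -4   1  -4  -3   6  -3   2   1  -2  -2  -3  -3  -2  -1   4  -3   0
K  -1  -3   0   1  -3  -2  -1  -3   6  -2  -1   0  -1   1   3   0   0  -2  -2  -1
L  -2  -2  -3  -2   2  -4  -2   2  -2   6   3  -3  -4  -2  -2  -3  -1   2  -1   0
M  -1  -3  -3  -2   0  -2   1   1  -1   3   7  -2  -2  -1  -1  -2  -1   1  -2   1
N  -1  -2   2  -1  -3   0   1  -2   0  -3  -2   8  -2   1   0   1   0  -3  -4  -2
P  -2  -5  -2   0  -4  -1  -2  -2  -1  -4  -2  -2  11  -2  -3  -1   0  -3  -4  -3
Q   0  -4  -1   2  -4  -2   0  -3   1  -2  -1   1  -2   8   2   1  -1  -3  -1  -1
R  -2  -3  -1  -1  -2  -3   0  -3   3  -2  -1   0  -3   2   9  -1  -2  -2  -2  -1
S   1  -1   0   0  -2   0  -1  -2   0  -3  -2   1  -1   1  -1   5   2  -1  -5  -2
T   0  -1  -1  -1  -1  -2  -2  -1   0  -1  -1   0   0  -1  -2   2   6   1  -4  -1
V   0  -2  -3  -3   0  -4  -4   4  -2   2   1  -3  -3  -3  -2  -1   1   5  -3  -1
W  -3  -6  -5  -2   1  -2  -5  -3  -2  -1  -2  -4  -4  -1  -2  -5  -4  -3  19   3
Y  -2  -4  -3  -2   4  -3   2   0  -1   0   1  -2  -3  -1  -1  -2  -1  -1   3   9
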