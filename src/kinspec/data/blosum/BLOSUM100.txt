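# BLOSUM100 amino-acid substitution scores, 20 standard residues, in 1/3 bit units.
# Derived from the published BLOSUM series (Henikoff & Henikoff 1992, BLOCKS database).
    A   C   D   E   F   G   H   I   K   L   M   N   P   Q   R   S   T   V   W   Y
A   8  -2  -5  -3  -5  -1  -4  -4  -2  -4  -3  -4  -2  -2  -3   1  -1  -2  -6  -5
C  -2  14  -8  -9  -4  -7  -8  -3  -8  -5  -4  -5  -8  -7  -8  -3  -3  -3  -7  -6
D  -5  -8  10   2  -8  -4  -3  -8  -3  -8  -8   1  -5  -2  -5  -2  -4  -8 -10  -7
E  -3  -9   2  10  -8  -6  -2  -7   0  -7  -5  -2  -4   2  -2  -2  -3  -5  -8  -7
F  -5  -4  -8  -8  11  -8  -4  -2  -6   0  -1  -7  -7  -6  -6  -5  -5  -3   0   4
G  -1  -7  -4  -6  -8   9  -6  -9  -5  -8  -7  -2  -6  -5  -6  -2  -5  -8  -7  -8
H  -4  -8  -3  -2  -4  -6  13  -7  -3  -6  -5   0  -5   1  -1  -3  -4  -7  -5   1
I  -4  -3  -8  -7  -2  -9  -7   8  -6   2   1  -7  -7  -6  -7  -5  -3   4  -6  -4
K  -2  -8  -3   0  -6  -5  -3  -6  10  -6  -4  -1  -3   2   3  -2  -3  -5  -8  -5
L  -4  -5  -8  -7   0  -8  -6   2  -6   8   3  -7  -7  -5  -6  -6  -4   0  -5  -4
M  -3  -4  -8  -5  -1  -7  -5   1  -4   3  12  -5  -5  -2  -4  -4  -2   0  -4  -5
N  -4  -5   1  -2  -7  -2   0  -7  -1  -7  -5  11  -5  -1  -2   0  -1  -7  -8  -5
P  -2  -8  -5  -4  -7  -6  -5  -7  -3  -7  -5  -5  12  -4  -5  -3  -4  -6  -8  -7
Q  -2  -7  -2   2  -6  -5   1  -6   2  -5  -2  -1  -4  11   0  -2  -3  -5  -5  -4
R  -3  -8  -5  -2  -6  -6  -1  -7   3  -6  -4  -2  -5   0  10  -3  -3  -6  -7  -5
S   1  -3  -2  -2  -5  -2  -3  -5  -2  -6  -4   0  -3  -2  -3   9   2  -4  -7  -5
T  -1  -3  -4  -3  -5  -5  -4  -3  -3  -4  -2  -1  -4  -3  -3   2   9  -1  -7  -5
V  -2  -3  -8  -5  -3  -8  -7   4  -5   0   0  -7  -6  -5  -6  -4  -1   8  -5  -5
W  -6  -7 -10  -8   0  -7  -5  -6  -8  -5  -4  -8  -8  -5  -7  -7  -7  -5  17   2
Y  -5  -6  -7  -7   4  -8   1  -4  -5  -4  -5  -5  -7  -4  -5  -5  -5  -5   2  12
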