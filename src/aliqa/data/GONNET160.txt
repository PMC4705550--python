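# Gonnet amino-acid substitution matrix (Gonnet, Cohen & Benner 1992,
# Science 256:1443-1445), in 1/10 units, 20 standard residues only.
# Values match the GONNET1992 table distributed with Biopython; this
# embedded file is the single source of truth for Gonnet scoring in
# this package (shipped here under the id GONNET160).
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V
A   2.4  -0.6  -0.3  -0.3   0.5  -0.2   0.0   0.5  -0.8  -0.8  -1.2  -0.4  -0.7  -2.3   0.3   1.1   0.6  -3.6  -2.2   0.1
R  -0.6   4.7   0.3  -0.3  -2.2   1.5   0.4  -1.0   0.6  -2.4  -2.2   2.7  -1.7  -3.2  -0.9  -0.2  -0.2  -1.6  -1.8  -2.0
N  -0.3   0.3   3.8   2.2  -1.8   0.7   0.9   0.4   1.2  -2.8  -3.0   0.8  -2.2  -3.1  -0.9   0.9   0.5  -3.6  -1.4  -2.2
D  -0.3  -0.3   2.2   4.7  -3.2   0.9   2.7   0.1   0.4  -3.8  -4.0   0.5  -3.0  -4.5  -0.7   0.5   0.0  -5.2  -2.8  -2.9
C   0.5  -2.2  -1.8  -3.2  11.5  -2.4  -3.0  -2.0  -1.3  -1.1  -1.5  -2.8  -0.9  -0.8  -3.1   0.1  -0.5  -1.0  -0.5   0.0
Q  -0.2   1.5   0.7   0.9  -2.4   2.7   1.7  -1.0   1.2  -1.9  -1.6   1.5  -1.0  -2.6  -0.2   0.2   0.0  -2.7  -1.7  -1.5
E   0.0   0.4   0.9   2.7  -3.0   1.7   3.6  -0.8   0.4  -2.7  -2.8   1.2  -2.0  -3.9  -0.5   0.2  -0.1  -4.3  -2.7  -1.9
G   0.5  -1.0   0.4   0.1  -2.0  -1.0  -0.8   6.6  -1.4  -4.5  -4.4  -1.1  -3.5  -5.2  -1.6   0.4  -1.1  -4.0  -4.0  -3.3
H  -0.8   0.6   1.2   0.4  -1.3   1.2   0.4  -1.4   6.0  -2.2  -1.9   0.6  -1.3  -0.1  -1.1  -0.2  -0.3  -0.8   2.2  -2.0
I  -0.8  -2.4  -2.8  -3.8  -1.1  -1.9  -2.7  -4.5  -2.2   4.0   2.8  -2.1   2.5   1.0  -2.6  -1.8  -0.6  -1.8  -0.7   3.1
L  -1.2  -2.2  -3.0  -4.0  -1.5  -1.6  -2.8  -4.4  -1.9   2.8   4.0  -2.1   2.8   2.0  -2.3  -2.1  -1.3  -0.7   0.0   1.8
K  -0.4   2.7   0.8   0.5  -2.8   1.5   1.2  -1.1   0.6  -2.1  -2.1   3.2  -1.4  -3.3  -0.6   0.1   0.1  -3.5  -2.1  -1.7
M  -0.7  -1.7  -2.2  -3.0  -0.9  -1.0  -2.0  -3.5  -1.3   2.5   2.8  -1.4   4.3   1.6  -2.4  -1.4  -0.6  -1.0  -0.2   1.6
F  -2.3  -3.2  -3.1  -4.5  -0.8  -2.6  -3.9  -5.2  -0.1   1.0   2.0  -3.3   1.6   7.0  -3.8  -2.8  -2.2   3.6   5.1   0.1
P   0.3  -0.9  -0.9  -0.7  -3.1  -0.2  -0.5  -1.6  -1.1  -2.6  -2.3  -0.6  -2.4  -3.8   7.6   0.4   0.1  -5.0  -3.1  -1.8
S   1.1  -0.2   0.9   0.5   0.1   0.2   0.2   0.4  -0.2  -1.8  -2.1   0.1  -1.4  -2.8   0.4   2.2   1.5  -3.3  -1.9  -1.0
T   0.6  -0.2   0.5   0.0  -0.5   0.0  -0.1  -1.1  -0.3  -0.6  -1.3   0.1  -0.6  -2.2   0.1   1.5   2.5  -3.5  -1.9   0.0
W  -3.6  -1.6  -3.6  -5.2  -1.0  -2.7  -4.3  -4.0  -0.8  -1.8  -0.7  -3.5  -1.0   3.6  -5.0  -3.3  -3.5  14.2   4.1  -2.6
Y  -2.2  -1.8  -1.4  -2.8  -0.5  -1.7  -2.7  -4.0   2.2  -0.7   0.0  -2.1  -0.2   5.1  -3.1  -1.9  -1.9   4.1   7.8  -1.1
V   0.1  -2.0  -2.2  -2.9   0.0  -1.5  -1.9  -3.3  -2.0   3.1   1.8  -1.7   1.6   0.1  -1.8  -1.0   0.0  -2.6  -1.1   3.4
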