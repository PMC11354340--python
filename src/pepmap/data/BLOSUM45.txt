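#  Matrix made by matblas from blosum45.iij
#  * column uses minimum score
#  BLOSUM Clustered Scoring Matrix in 1/3 Bit Units
#  Blocks Database = /data/blocks_5.0/blocks.dat
#  Cluster Percentage: >= 45
#  Entropy =   0.3795, Expected =  -0.2789
     A    R    N    D    C    Q    E    G    H    I    L    K    M    F    P    S    T    W    Y    V    B    Z    X    *
A  5.0 -2.0 -1.0 -2.0 -1.0 -1.0 -1.0  0.0 -2.0 -1.0 -1.0 -1.0 -1.0 -2.0 -1.0  1.0  0.0 -2.0 -2.0  0.0 -1.0 -1.0  0.0 -5.0
R -2.0  7.0  0.0 -1.0 -3.0  1.0  0.0 -2.0  0.0 -3.0 -2.0  3.0 -1.0 -2.0 -2.0 -1.0 -1.0 -2.0 -1.0 -2.0 -1.0  0.0 -1.0 -5.0
N -1.0  0.0  6.0  2.0 -2.0  0.0  0.0  0.0  1.0 -2.0 -3.0  0.0 -2.0 -2.0 -2.0  1.0  0.0 -4.0 -2.0 -3.0  4.0  0.0 -1.0 -5.0
D -2.0 -1.0  2.0  7.0 -3.0  0.0  2.0 -1.0  0.0 -4.0 -3.0  0.0 -3.0 -4.0 -1.0  0.0 -1.0 -4.0 -2.0 -3.0  5.0  1.0 -1.0 -5.0
C -1.0 -3.0 -2.0 -3.0 12.0 -3.0 -3.0 -3.0 -3.0 -3.0 -2.0 -3.0 -2.0 -2.0 -4.0 -1.0 -1.0 -5.0 -3.0 -1.0 -2.0 -3.0 -2.0 -5.0
Q -1.0  1.0  0.0  0.0 -3.0  6.0  2.0 -2.0  1.0 -2.0 -2.0  1.0  0.0 -4.0 -1.0  0.0 -1.0 -2.0 -1.0 -3.0  0.0  4.0 -1.0 -5.0
E -1.0  0.0  0.0  2.0 -3.0  2.0  6.0 -2.0  0.0 -3.0 -2.0  1.0 -2.0 -3.0  0.0  0.0 -1.0 -3.0 -2.0 -3.0  1.0  4.0 -1.0 -5.0
G  0.0 -2.0  0.0 -1.0 -3.0 -2.0 -2.0  7.0 -2.0 -4.0 -3.0 -2.0 -2.0 -3.0 -2.0  0.0 -2.0 -2.0 -3.0 -3.0 -1.0 -2.0 -1.0 -5.0
H -2.0  0.0  1.0  0.0 -3.0  1.0  0.0 -2.0 10.0 -3.0 -2.0 -1.0  0.0 -2.0 -2.0 -1.0 -2.0 -3.0  2.0 -3.0  0.0  0.0 -1.0 -5.0
I -1.0 -3.0 -2.0 -4.0 -3.0 -2.0 -3.0 -4.0 -3.0  5.0  2.0 -3.0  2.0  0.0 -2.0 -2.0 -1.0 -2.0  0.0  3.0 -3.0 -3.0 -1.0 -5.0
L -1.0 -2.0 -3.0 -3.0 -2.0 -2.0 -2.0 -3.0 -2.0  2.0  5.0 -3.0  2.0  1.0 -3.0 -3.0 -1.0 -2.0  0.0  1.0 -3.0 -2.0 -1.0 -5.0
K -1.0  3.0  0.0  0.0 -3.0  1.0  1.0 -2.0 -1.0 -3.0 -3.0  5.0 -1.0 -3.0 -1.0 -1.0 -1.0 -2.0 -1.0 -2.0  0.0  1.0 -1.0 -5.0
M -1.0 -1.0 -2.0 -3.0 -2.0  0.0 -2.0 -2.0  0.0  2.0  2.0 -1.0  6.0  0.0 -2.0 -2.0 -1.0 -2.0  0.0  1.0 -2.0 -1.0 -1.0 -5.0
F -2.0 -2.0 -2.0 -4.0 -2.0 -4.0 -3.0 -3.0 -2.0  0.0  1.0 -3.0  0.0  8.0 -3.0 -2.0 -1.0  1.0  3.0  0.0 -3.0 -3.0 -1.0 -5.0
P -1.0 -2.0 -2.0 -1.0 -4.0 -1.0  0.0 -2.0 -2.0 -2.0 -3.0 -1.0 -2.0 -3.0  9.0 -1.0 -1.0 -3.0 -3.0 -3.0 -2.0 -1.0 -1.0 -5.0
S  1.0 -1.0  1.0  0.0 -1.0  0.0  0.0  0.0 -1.0 -2.0 -3.0 -1.0 -2.0 -2.0 -1.0  4.0  2.0 -4.0 -2.0 -1.0  0.0  0.0  0.0 -5.0
T  0.0 -1.0  0.0 -1.0 -1.0 -1.0 -1.0 -2.0 -2.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0  2.0  5.0 -3.0 -1.0  0.0  0.0 -1.0  0.0 -5.0
W -2.0 -2.0 -4.0 -4.0 -5.0 -2.0 -3.0 -2.0 -3.0 -2.0 -2.0 -2.0 -2.0  1.0 -3.0 -4.0 -3.0 15.0  3.0 -3.0 -4.0 -2.0 -2.0 -5.0
Y -2.0 -1.0 -2.0 -2.0 -3.0 -1.0 -2.0 -3.0  2.0  0.0  0.0 -1.0  0.0  3.0 -3.0 -2.0 -1.0  3.0  8.0 -1.0 -2.0 -2.0 -1.0 -5.0
V  0.0 -2.0 -3.0 -3.0 -1.0 -3.0 -3.0 -3.0 -3.0  3.0  1.0 -2.0  1.0  0.0 -3.0 -1.0  0.0 -3.0 -1.0  5.0 -3.0 -3.0 -1.0 -5.0
B -1.0 -1.0  4.0  5.0 -2.0  0.0  1.0 -1.0  0.0 -3.0 -3.0  0.0 -2.0 -3.0 -2.0  0.0  0.0 -4.0 -2.0 -3.0  4.0  2.0 -1.0 -5.0
Z -1.0  0.0  0.0  1.0 -3.0  4.0  4.0 -2.0  0.0 -3.0 -2.0  1.0 -1.0 -3.0 -1.0  0.0 -1.0 -2.0 -2.0 -3.0  2.0  4.0 -1.0 -5.0
X  0.0 -1.0 -1.0 -1.0 -2.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0 -1.0  0.0  0.0 -2.0 -1.0 -1.0 -1.0 -1.0 -1.0 -5.0
* -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0 -5.0  1.0
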