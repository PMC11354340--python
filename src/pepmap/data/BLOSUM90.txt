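#  Matrix made by matblas from blosum90.iij
#  * column uses minimum score
#  BLOSUM Clustered Scoring Matrix in 1/2 Bit Units
#  Blocks Database = /data/blocks_5.0/blocks.dat
#  Cluster Percentage: >= 90
#  Entropy =   1.1806, Expected =  -0.8887
     A    R    N    D    C    Q    E    G    H    I    L    K    M    F    P    S    T    W    Y    V    B    Z    X    *
A  5.0 -2.0 -2.0 -3.0 -1.0 -1.0 -1.0  0.0 -2.0 -2.0 -2.0 -1.0 -2.0 -3.0 -1.0  1.0  0.0 -4.0 -3.0 -1.0 -2.0 -1.0 -1.0 -6.0
R -2.0  6.0 -1.0 -3.0 -5.0  1.0 -1.0 -3.0  0.0 -4.0 -3.0  2.0 -2.0 -4.0 -3.0 -1.0 -2.0 -4.0 -3.0 -3.0 -2.0  0.0 -2.0 -6.0
N -2.0 -1.0  7.0  1.0 -4.0  0.0 -1.0 -1.0  0.0 -4.0 -4.0  0.0 -3.0 -4.0 -3.0  0.0  0.0 -5.0 -3.0 -4.0  4.0 -1.0 -2.0 -6.0
D -3.0 -3.0  1.0  7.0 -5.0 -1.0  1.0 -2.0 -2.0 -5.0 -5.0 -1.0 -4.0 -5.0 -3.0 -1.0 -2.0 -6.0 -4.0 -5.0  4.0  0.0 -2.0 -6.0
C -1.0 -5.0 -4.0 -5.0  9.0 -4.0 -6.0 -4.0 -5.0 -2.0 -2.0 -4.0 -2.0 -3.0 -4.0 -2.0 -2.0 -4.0 -4.0 -2.0 -4.0 -5.0 -3.0 -6.0
Q -1.0  1.0  0.0 -1.0 -4.0  7.0  2.0 -3.0  1.0 -4.0 -3.0  1.0  0.0 -4.0 -2.0 -1.0 -1.0 -3.0 -3.0 -3.0 -1.0  4.0 -1.0 -6.0
E -1.0 -1.0 -1.0  1.0 -6.0  2.0  6.0 -3.0 -1.0 -4.0 -4.0  0.0 -3.0 -5.0 -2.0 -1.0 -1.0 -5.0 -4.0 -3.0  0.0  4.0 -2.0 -6.0
G  0.0 -3.0 -1.0 -2.0 -4.0 -3.0 -3.0  6.0 -3.0 -5.0 -5.0 -2.0 -4.0 -5.0 -3.0 -1.0 -3.0 -4.0 -5.0 -5.0 -2.0 -3.0 -2.0 -6.0
H -2.0  0.0  0.0 -2.0 -5.0  1.0 -1.0 -3.0  8.0 -4.0 -4.0 -1.0 -3.0 -2.0 -3.0 -2.0 -2.0 -3.0  1.0 -4.0 -1.0  0.0 -2.0 -6.0
I -2.0 -4.0 -4.0 -5.0 -2.0 -4.0 -4.0 -5.0 -4.0  5.0  1.0 -4.0  1.0 -1.0 -4.0 -3.0 -1.0 -4.0 -2.0  3.0 -5.0 -4.0 -2.0 -6.0
L -2.0 -3.0 -4.0 -5.0 -2.0 -3.0 -4.0 -5.0 -4.0  1.0  5.0 -3.0  2.0  0.0 -4.0 -3.0 -2.0 -3.0 -2.0  0.0 -5.0 -4.0 -2.0 -6.0
K -1.0  2.0  0.0 -1.0 -4.0  1.0  0.0 -2.0 -1.0 -4.0 -3.0  6.0 -2.0 -4.0 -2.0 -1.0 -1.0 -5.0 -3.0 -3.0 -1.0  1.0 -1.0 -6.0
M -2.0 -2.0 -3.0 -4.0 -2.0  0.0 -3.0 -4.0 -3.0  1.0  2.0 -2.0  7.0 -1.0 -3.0 -2.0 -1.0 -2.0 -2.0  0.0 -4.0 -2.0 -1.0 -6.0
F -3.0 -4.0 -4.0 -5.0 -3.0 -4.0 -5.0 -5.0 -2.0 -1.0  0.0 -4.0 -1.0  7.0 -4.0 -3.0 -3.0  0.0  3.0 -2.0 -4.0 -4.0 -2.0 -6.0
P -1.0 -3.0 -3.0 -3.0 -4.0 -2.0 -2.0 -3.0 -3.0 -4.0 -4.0 -2.0 -3.0 -4.0  8.0 -2.0 -2.0 -5.0 -4.0 -3.0 -3.0 -2.0 -2.0 -6.0
S  1.0 -1.0  0.0 -1.0 -2.0 -1.0 -1.0 -1.0 -2.0 -3.0 -3.0 -1.0 -2.0 -3.0 -2.0  5.0  1.0 -4.0 -3.0 -2.0  0.0 -1.0 -1.0 -6.0
T  0.0 -2.0  0.0 -2.0 -2.0 -1.0 -1.0 -3.0 -2.0 -1.0 -2.0 -1.0 -1.0 -3.0 -2.0  1.0  6.0 -4.0 -2.0 -1.0 -1.0 -1.0 -1.0 -6.0
W -4.0 -4.0 -5.0 -6.0 -4.0 -3.0 -5.0 -4.0 -3.0 -4.0 -3.0 -5.0 -2.0  0.0 -5.0 -4.0 -4.0 11.0  2.0 -3.0 -6.0 -4.0 -3.0 -6.0
Y -3.0 -3.0 -3.0 -4.0 -4.0 -3.0 -4.0 -5.0  1.0 -2.0 -2.0 -3.0 -2.0  3.0 -4.0 -3.0 -2.0  2.0  8.0 -3.0 -4.0 -3.0 -2.0 -6.0
V -1.0 -3.0 -4.0 -5.0 -2.0 -3.0 -3.0 -5.0 -4.0  3.0  0.0 -3.0  0.0 -2.0 -3.0 -2.0 -1.0 -3.0 -3.0  5.0 -4.0 -3.0 -2.0 -6.0
B -2.0 -2.0  4.0  4.0 -4.0 -1.0  0.0 -2.0 -1.0 -5.0 -5.0 -1.0 -4.0 -4.0 -3.0  0.0 -1.0 -6.0 -4.0 -4.0  4.0  0.0 -2.0 -6.0
Z -1.0  0.0 -1.0  0.0 -5.0  4.0  4.0 -3.0  0.0 -4.0 -4.0  1.0 -2.0 -4.0 -2.0 -1.0 -1.0 -4.0 -3.0 -3.0  0.0  4.0 -1.0 -6.0
X -1.0 -2.0 -2.0 -2.0 -3.0 -1.0 -2.0 -2.0 -2.0 -2.0 -2.0 -1.0 -1.0 -2.0 -2.0 -1.0 -1.0 -3.0 -2.0 -2.0 -2.0 -1.0 -2.0 -6.0
* -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0 -6.0  1.0
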