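#  
#  This matrix was produced by "pam" Version 1.0.6 [28-Jul-93]
#  
#  PAM 30 substitution matrix, scale = ln(2)/2 = 0.346574
#  
#  Expected score = -5.06, Entropy = 2.57 bits
#  
#  Lowest score = -17, Highest score = 13
#  
      A     R     N     D     C     Q     E     G     H     I     L     K     M     F     P     S     T     W     Y     V     B     Z     X     *
A   6.0  -7.0  -4.0  -3.0  -6.0  -4.0  -2.0  -2.0  -7.0  -5.0  -6.0  -7.0  -5.0  -8.0  -2.0   0.0  -1.0 -13.0  -8.0  -2.0  -3.0  -3.0  -3.0 -17.0
R  -7.0   8.0  -6.0 -10.0  -8.0  -2.0  -9.0  -9.0  -2.0  -5.0  -8.0   0.0  -4.0  -9.0  -4.0  -3.0  -6.0  -2.0 -10.0  -8.0  -7.0  -4.0  -6.0 -17.0
N  -4.0  -6.0   8.0   2.0 -11.0  -3.0  -2.0  -3.0   0.0  -5.0  -7.0  -1.0  -9.0  -9.0  -6.0   0.0  -2.0  -8.0  -4.0  -8.0   6.0  -3.0  -3.0 -17.0
D  -3.0 -10.0   2.0   8.0 -14.0  -2.0   2.0  -3.0  -4.0  -7.0 -12.0  -4.0 -11.0 -15.0  -8.0  -4.0  -5.0 -15.0 -11.0  -8.0   6.0   1.0  -5.0 -17.0
C  -6.0  -8.0 -11.0 -14.0  10.0 -14.0 -14.0  -9.0  -7.0  -6.0 -15.0 -14.0 -13.0 -13.0  -8.0  -3.0  -8.0 -15.0  -4.0  -6.0 -12.0 -14.0  -9.0 -17.0
Q  -4.0  -2.0  -3.0  -2.0 -14.0   8.0   1.0  -7.0   1.0  -8.0  -5.0  -3.0  -4.0 -13.0  -3.0  -5.0  -5.0 -13.0 -12.0  -7.0  -3.0   6.0  -5.0 -17.0
E  -2.0  -9.0  -2.0   2.0 -14.0   1.0   8.0  -4.0  -5.0  -5.0  -9.0  -4.0  -7.0 -14.0  -5.0  -4.0  -6.0 -17.0  -8.0  -6.0   1.0   6.0  -5.0 -17.0
G  -2.0  -9.0  -3.0  -3.0  -9.0  -7.0  -4.0   6.0  -9.0 -11.0 -10.0  -7.0  -8.0  -9.0  -6.0  -2.0  -6.0 -15.0 -14.0  -5.0  -3.0  -5.0  -5.0 -17.0
H  -7.0  -2.0   0.0  -4.0  -7.0   1.0  -5.0  -9.0   9.0  -9.0  -6.0  -6.0 -10.0  -6.0  -4.0  -6.0  -7.0  -7.0  -3.0  -6.0  -1.0  -1.0  -5.0 -17.0
I  -5.0  -5.0  -5.0  -7.0  -6.0  -8.0  -5.0 -11.0  -9.0   8.0  -1.0  -6.0  -1.0  -2.0  -8.0  -7.0  -2.0 -14.0  -6.0   2.0  -6.0  -6.0  -5.0 -17.0
L  -6.0  -8.0  -7.0 -12.0 -15.0  -5.0  -9.0 -10.0  -6.0  -1.0   7.0  -8.0   1.0  -3.0  -7.0  -8.0  -7.0  -6.0  -7.0  -2.0  -9.0  -7.0  -6.0 -17.0
K  -7.0   0.0  -1.0  -4.0 -14.0  -3.0  -4.0  -7.0  -6.0  -6.0  -8.0   7.0  -2.0 -14.0  -6.0  -4.0  -3.0 -12.0  -9.0  -9.0  -2.0  -4.0  -5.0 -17.0
M  -5.0  -4.0  -9.0 -11.0 -13.0  -4.0  -7.0  -8.0 -10.0  -1.0   1.0  -2.0  11.0  -4.0  -8.0  -5.0  -4.0 -13.0 -11.0  -1.0 -10.0  -5.0  -5.0 -17.0
F  -8.0  -9.0  -9.0 -15.0 -13.0 -13.0 -14.0  -9.0  -6.0  -2.0  -3.0 -14.0  -4.0   9.0 -10.0  -6.0  -9.0  -4.0   2.0  -8.0 -10.0 -13.0  -8.0 -17.0
P  -2.0  -4.0  -6.0  -8.0  -8.0  -3.0  -5.0  -6.0  -4.0  -8.0  -7.0  -6.0  -8.0 -10.0   8.0  -2.0  -4.0 -14.0 -13.0  -6.0  -7.0  -4.0  -5.0 -17.0
S   0.0  -3.0   0.0  -4.0  -3.0  -5.0  -4.0  -2.0  -6.0  -7.0  -8.0  -4.0  -5.0  -6.0  -2.0   6.0   0.0  -5.0  -7.0  -6.0  -1.0  -5.0  -3.0 -17.0
T  -1.0  -6.0  -2.0  -5.0  -8.0  -5.0  -6.0  -6.0  -7.0  -2.0  -7.0  -3.0  -4.0  -9.0  -4.0   0.0   7.0 -13.0  -6.0  -3.0  -3.0  -6.0  -4.0 -17.0
W -13.0  -2.0  -8.0 -15.0 -15.0 -13.0 -17.0 -15.0  -7.0 -14.0  -6.0 -12.0 -13.0  -4.0 -14.0  -5.0 -13.0  13.0  -5.0 -15.0 -10.0 -14.0 -11.0 -17.0
Y  -8.0 -10.0  -4.0 -11.0  -4.0 -12.0  -8.0 -14.0  -3.0  -6.0  -7.0  -9.0 -11.0   2.0 -13.0  -7.0  -6.0  -5.0  10.0  -7.0  -6.0  -9.0  -7.0 -17.0
V  -2.0  -8.0  -8.0  -8.0  -6.0  -7.0  -6.0  -5.0  -6.0   2.0  -2.0  -9.0  -1.0  -8.0  -6.0  -6.0  -3.0 -15.0  -7.0   7.0  -8.0  -6.0  -5.0 -17.0
B  -3.0  -7.0   6.0   6.0 -12.0  -3.0   1.0  -3.0  -1.0  -6.0  -9.0  -2.0 -10.0 -10.0  -7.0  -1.0  -3.0 -10.0  -6.0  -8.0   6.0   0.0  -5.0 -17.0
Z  -3.0  -4.0  -3.0   1.0 -14.0   6.0   6.0  -5.0  -1.0  -6.0  -7.0  -4.0  -5.0 -13.0  -4.0  -5.0  -6.0 -14.0  -9.0  -6.0   0.0   6.0  -5.0 -17.0
X  -3.0  -6.0  -3.0  -5.0  -9.0  -5.0  -5.0  -5.0  -5.0  -5.0  -6.0  -5.0  -5.0  -8.0  -5.0  -3.0  -4.0 -11.0  -7.0  -5.0  -5.0  -5.0  -5.0 -17.0
* -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0 -17.0   1.0
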