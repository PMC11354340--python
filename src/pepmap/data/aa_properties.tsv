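# Per-residue constants: average residue mass (Da, monomer minus water) and
# Kyte-Doolittle hydropathy.
aa	avg_mass	kd_hydropathy
A	71.0788	1.8
R	156.1875	-4.5
N	114.1038	-3.5
D	115.0886	-3.5
C	103.1388	2.5
Q	128.1307	-3.5
E	129.1155	-3.5
G	57.0519	-0.4
H	137.1411	-3.2
I	113.1594	4.5
L	113.1594	3.8
K	128.1741	-3.9
M	131.1926	1.9
F	147.1766	2.8
P	97.1167	-1.6
S	87.0782	-0.8
T	101.1051	-0.7
W	186.2132	-0.9
Y	163.1760	-1.3
V	99.1326	4.2
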