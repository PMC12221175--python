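residue	class
A	1
C	7
D	6
E	6
F	2
G	1
H	4
I	2
K	5
L	2
M	3
N	4
P	2
Q	4
R	5
S	3
T	3
V	1
W	4
Y	3
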