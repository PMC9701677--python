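residue	max_sidechain_sasa_A2
A	50.585
R	194.617
N	105.062
D	98.614
C	85.804
Q	132.298
E	123.818
G	29.671
H	132.617
I	116.594
L	130.973
K	153.74
M	142.481
F	160.905
P	71.238
S	62.711
T	90.204
W	206.049
Y	173.422
V	101.824
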