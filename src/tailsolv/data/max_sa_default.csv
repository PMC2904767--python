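code1,max_sa_a2
A,248.17063134211045
C,276.1291343699685
D,303.28746720397254
E,317.9815521288101
F,350.40377922453956
G,218.375570265924
H,335.4299459458754
I,310.1210975049723
K,322.30378409955154
L,310.1210975049723
M,312.0695603926185
N,304.05110460225615
P,292.1503707123487
Q,318.7109658021236
R,344.636796860253
S,269.3129752511135
T,289.614779500664
V,292.1503707123487
W,386.8858485455919
Y,359.8712880813855
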