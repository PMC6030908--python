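# Per-position mismatch weights for the MIT hit score, position 1 = PAM-distal.
# The widely reproduced experimental 20-mer weight matrix; note several
# PAM-distal positions carry weight 0 (a single mismatch there scores 100).
position	weight
1	0.000
2	0.000
3	0.014
4	0.000
5	0.000
6	0.395
7	0.317
8	0.000
9	0.389
10	0.079
11	0.445
12	0.508
13	0.613
14	0.851
15	0.732
16	0.828
17	0.615
18	0.804
19	0.685
20	0.583
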