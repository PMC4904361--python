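# J35 elongated triangular orthobicupola | Johnson | id 66
0.57735026919 -1.23358113847e-16 1.31649658093
-0.288675134595 0.5 1.31649658093
-0.288675134595 -0.5 1.31649658093
0.866025403784 0.5 0.5
6.43162928035e-17 1 0.5
-0.866025403784 0.5 0.5
-0.866025403784 -0.5 0.5
-1.80613067026e-16 -1 0.5
0.866025403784 -0.5 0.5
0.866025403784 0.5 -0.5
6.43162928035e-17 1 -0.5
-0.866025403784 0.5 -0.5
-0.866025403784 -0.5 -0.5
-1.80613067026e-16 -1 -0.5
0.866025403784 -0.5 -0.5
0.57735026919 -1.23358113847e-16 -1.31649658093
-0.288675134595 0.5 -1.31649658093
-0.288675134595 -0.5 -1.31649658093
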