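# J14 elongated triangular bipyramid | Johnson | id 45
0.57735026919 -5.55111512313e-17 0.5
-0.288675134595 0.5 0.5
-0.288675134595 -0.5 0.5
0.57735026919 -5.55111512313e-17 -0.5
-0.288675134595 0.5 -0.5
-0.288675134595 -0.5 -0.5
3.46944695195e-17 -5.55111512313e-17 1.31649658093
3.46944695195e-17 -5.55111512313e-17 -1.31649658093
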