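# J27 triangular orthobicupola | Johnson | id 58
0.866025403784 0.5 -1.85037170771e-17
8.43619863037e-17 1 -1.85037170771e-17
-0.866025403784 0.5 -1.85037170771e-17
-0.866025403784 -0.5 -1.85037170771e-17
-1.60567373526e-16 -1 -1.85037170771e-17
0.866025403784 -0.5 -1.85037170771e-17
0.57735026919 -1.2952601954e-16 0.816496580928
-0.288675134595 0.5 0.816496580928
-0.288675134595 -0.5 0.816496580928
0.57735026919 -1.2952601954e-16 -0.816496580928
-0.288675134595 0.5 -0.816496580928
-0.288675134595 -0.5 -0.816496580928
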