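# J36 elongated triangular gyrobicupola | Johnson | id 67
0.57735026919 -9.86864910778e-17 1.31649658093
-0.288675134595 0.5 1.31649658093
-0.288675134595 -0.5 1.31649658093
0.866025403784 0.5 0.5
7.35681513421e-17 1 0.5
-0.866025403784 0.5 0.5
-0.866025403784 -0.5 0.5
-1.71361208487e-16 -1 0.5
0.866025403784 -0.5 0.5
0.866025403784 0.5 -0.5
7.35681513421e-17 1 -0.5
-0.866025403784 0.5 -0.5
-0.866025403784 -0.5 -0.5
-1.71361208487e-16 -1 -0.5
0.866025403784 -0.5 -0.5
0.288675134595 0.5 -1.31649658093
-0.57735026919 -2.79814751628e-17 -1.31649658093
0.288675134595 -0.5 -1.31649658093
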