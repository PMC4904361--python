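# J44 gyroelongated triangular bicupola | Johnson | id 75
0.57735026919 -6.7846962616e-17 1.24429641951
-0.288675134595 0.5 1.24429641951
-0.288675134595 -0.5 1.24429641951
0.866025403784 0.5 0.427799838584
9.79639530788e-17 1 0.427799838584
-0.866025403784 0.5 0.427799838584
-0.866025403784 -0.5 0.427799838584
-1.46965406751e-16 -1 0.427799838584
0.866025403784 -0.5 0.427799838584
0.5 0.866025403784 -0.427799838584
-0.5 0.866025403784 -0.427799838584
-1 5.46177172988e-17 -0.427799838584
-0.5 -0.866025403784 -0.427799838584
0.5 -0.866025403784 -0.427799838584
1 -3.12776322445e-16 -0.427799838584
0.5 0.288675134595 -1.24429641951
-0.5 0.288675134595 -1.24429641951
-6.93259107511e-17 -0.57735026919 -1.24429641951
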