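# J22 gyroelongated triangular cupola | Johnson | id 53
0.57735026919 -7.24892179814e-17 0.995437135609
-0.288675134595 0.5 0.995437135609
-0.288675134595 -0.5 0.995437135609
0.866025403784 0.5 0.178940554681
1.05641260942e-16 1 0.178940554681
-0.866025403784 0.5 0.178940554681
-0.866025403784 -0.5 0.178940554681
-1.39288098887e-16 -1 0.178940554681
0.866025403784 -0.5 0.178940554681
0.5 0.866025403784 -0.676659122486
-0.5 0.866025403784 -0.676659122486
-1 4.99754619334e-17 -0.676659122486
-0.5 -0.866025403784 -0.676659122486
0.5 -0.866025403784 -0.676659122486
1 -3.17418577811e-16 -0.676659122486
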