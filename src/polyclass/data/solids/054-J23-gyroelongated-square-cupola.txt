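# J23 gyroelongated square cupola | Johnson | id 54
0.707106781187 6.04097025132e-17 0.909803652894
1.09911184289e-16 0.707106781187 0.909803652894
-0.707106781187 1.47005308137e-16 0.909803652894
-6.32800269578e-17 -0.707106781187 0.909803652894
1.20710678119 0.5 0.202696871708
0.5 1.20710678119 0.202696871708
-0.5 1.20710678119 0.202696871708
-1.20710678119 0.5 0.202696871708
-1.20710678119 -0.5 0.202696871708
-0.5 -1.20710678119 0.202696871708
0.5 -1.20710678119 0.202696871708
1.20710678119 -0.5 0.202696871708
0.923879532511 0.923879532511 -0.657598698155
1.46617289119e-16 1.30656296488 -0.657598698155
-0.923879532511 0.923879532511 -0.657598698155
-1.30656296488 2.20417517795e-16 -0.657598698155
-0.923879532511 -0.923879532511 -0.657598698155
-1.73398341446e-16 -1.30656296488 -0.657598698155
0.923879532511 -0.923879532511 -0.657598698155
1.30656296488 -2.59605928051e-16 -0.657598698155
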