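# J45 gyroelongated square bicupola | Johnson | id 76
0.707106781187 4.16333634234e-17 1.13725456612
9.64959894084e-17 0.707106781187 1.13725456612
-0.707106781187 1.28228969047e-16 1.13725456612
-7.66952218387e-17 -0.707106781187 1.13725456612
1.20710678119 0.5 0.430147784931
0.5 1.20710678119 0.430147784931
-0.5 1.20710678119 0.430147784931
-1.20710678119 0.5 0.430147784931
-1.20710678119 -0.5 0.430147784931
-0.5 -1.20710678119 0.430147784931
0.5 -1.20710678119 0.430147784931
1.20710678119 -0.5 0.430147784931
0.923879532511 0.923879532511 -0.430147784931
1.33202094238e-16 1.30656296488 -0.430147784931
-0.923879532511 0.923879532511 -0.430147784931
-1.30656296488 2.01641178705e-16 -0.430147784931
-0.923879532511 -0.923879532511 -0.430147784931
-1.86813536326e-16 -1.30656296488 -0.430147784931
0.923879532511 -0.923879532511 -0.430147784931
1.30656296488 -2.78382267141e-16 -0.430147784931
0.653281482438 0.270598050073 -1.13725456612
-0.270598050073 0.653281482438 -1.13725456612
-0.653281482438 -0.270598050073 -1.13725456612
0.270598050073 -0.653281482438 -1.13725456612
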