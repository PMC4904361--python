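# J4 square cupola | Johnson | id 35
1.20710678119 0.5 -0.235702260396
0.5 1.20710678119 -0.235702260396
-0.5 1.20710678119 -0.235702260396
-1.20710678119 0.5 -0.235702260396
-1.20710678119 -0.5 -0.235702260396
-0.5 -1.20710678119 -0.235702260396
0.5 -1.20710678119 -0.235702260396
1.20710678119 -0.5 -0.235702260396
0.707106781187 3.70074341542e-17 0.471404520791
1.09633404746e-16 0.707106781187 0.471404520791
-0.707106781187 1.23603039778e-16 0.471404520791
-6.35578065011e-17 -0.707106781187 0.471404520791
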