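# J37 elongated square gyrobicupola | Johnson | id 68
0.707106781187 2.31296463464e-17 1.20710678119
9.41830247738e-17 0.707106781187 1.20710678119
-0.707106781187 1.0972525197e-16 1.20710678119
-7.90081864733e-17 -0.707106781187 1.20710678119
1.20710678119 0.5 0.5
0.5 1.20710678119 0.5
-0.5 1.20710678119 0.5
-1.20710678119 0.5 0.5
-1.20710678119 -0.5 0.5
-0.5 -1.20710678119 0.5
0.5 -1.20710678119 0.5
1.20710678119 -0.5 0.5
1.20710678119 0.5 -0.5
0.5 1.20710678119 -0.5
-0.5 1.20710678119 -0.5
-1.20710678119 0.5 -0.5
-1.20710678119 -0.5 -0.5
-0.5 -1.20710678119 -0.5
0.5 -1.20710678119 -0.5
1.20710678119 -0.5 -0.5
0.5 0.5 -1.20710678119
-0.5 0.5 -1.20710678119
-0.5 -0.5 -1.20710678119
0.5 -0.5 -1.20710678119
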