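# J66 augmented truncated cube | Johnson | id 97
0.5 1.20710678119 0.933647700848
0.5 1.20710678119 -1.48056586153
0.5 -1.20710678119 0.933647700848
0.5 -1.20710678119 -1.48056586153
-0.5 1.20710678119 0.933647700848
-0.5 1.20710678119 -1.48056586153
-0.5 -1.20710678119 0.933647700848
-0.5 -1.20710678119 -1.48056586153
1.20710678119 0.5 0.933647700848
1.20710678119 0.5 -1.48056586153
1.20710678119 -0.5 0.933647700848
1.20710678119 -0.5 -1.48056586153
-1.20710678119 0.5 0.933647700848
-1.20710678119 0.5 -1.48056586153
-1.20710678119 -0.5 0.933647700848
-1.20710678119 -0.5 -1.48056586153
1.20710678119 1.20710678119 0.226540919661
1.20710678119 1.20710678119 -0.773459080339
1.20710678119 -1.20710678119 0.226540919661
1.20710678119 -1.20710678119 -0.773459080339
-1.20710678119 1.20710678119 0.226540919661
-1.20710678119 1.20710678119 -0.773459080339
-1.20710678119 -1.20710678119 0.226540919661
-1.20710678119 -1.20710678119 -0.773459080339
0.707106781187 7.45395407034e-17 1.64075448203
-1.09039761347e-17 0.707106781187 1.64075448203
-0.707106781187 -3.9650822308e-18 1.64075448203
-1.09039761347e-17 -0.707106781187 1.64075448203
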