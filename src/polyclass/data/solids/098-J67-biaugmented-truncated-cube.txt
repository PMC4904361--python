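# J67 biaugmented truncated cube | Johnson | id 98
0.5 1.20710678119 1.20710678119
0.5 1.20710678119 -1.20710678119
0.5 -1.20710678119 1.20710678119
0.5 -1.20710678119 -1.20710678119
-0.5 1.20710678119 1.20710678119
-0.5 1.20710678119 -1.20710678119
-0.5 -1.20710678119 1.20710678119
-0.5 -1.20710678119 -1.20710678119
1.20710678119 0.5 1.20710678119
1.20710678119 0.5 -1.20710678119
1.20710678119 -0.5 1.20710678119
1.20710678119 -0.5 -1.20710678119
-1.20710678119 0.5 1.20710678119
-1.20710678119 0.5 -1.20710678119
-1.20710678119 -0.5 1.20710678119
-1.20710678119 -0.5 -1.20710678119
1.20710678119 1.20710678119 0.5
1.20710678119 1.20710678119 -0.5
1.20710678119 -1.20710678119 0.5
1.20710678119 -1.20710678119 -0.5
-1.20710678119 1.20710678119 0.5
-1.20710678119 1.20710678119 -0.5
-1.20710678119 -1.20710678119 0.5
-1.20710678119 -1.20710678119 -0.5
0.707106781187 6.11573881744e-17 1.91421356237
-2.62313093877e-17 0.707106781187 1.91421356237
-0.707106781187 -1.73472347598e-17 1.91421356237
-2.62313093877e-17 -0.707106781187 1.91421356237
-0.707106781187 3.81639164715e-17 -1.91421356237
5.70354174591e-17 0.707106781187 -1.91421356237
0.707106781187 1.16668539406e-16 -1.91421356237
1.7479235186e-16 -0.707106781187 -1.91421356237
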