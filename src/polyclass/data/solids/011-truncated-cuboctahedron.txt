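# truncated cuboctahedron | Archimedean | id 11
0.5 1.20710678119 1.91421356237
0.5 1.20710678119 -1.91421356237
0.5 -1.20710678119 1.91421356237
0.5 -1.20710678119 -1.91421356237
-0.5 1.20710678119 1.91421356237
-0.5 1.20710678119 -1.91421356237
-0.5 -1.20710678119 1.91421356237
-0.5 -1.20710678119 -1.91421356237
0.5 1.91421356237 1.20710678119
0.5 1.91421356237 -1.20710678119
0.5 -1.91421356237 1.20710678119
0.5 -1.91421356237 -1.20710678119
-0.5 1.91421356237 1.20710678119
-0.5 1.91421356237 -1.20710678119
-0.5 -1.91421356237 1.20710678119
-0.5 -1.91421356237 -1.20710678119
1.20710678119 0.5 1.91421356237
1.20710678119 0.5 -1.91421356237
1.20710678119 -0.5 1.91421356237
1.20710678119 -0.5 -1.91421356237
-1.20710678119 0.5 1.91421356237
-1.20710678119 0.5 -1.91421356237
-1.20710678119 -0.5 1.91421356237
-1.20710678119 -0.5 -1.91421356237
1.20710678119 1.91421356237 0.5
1.20710678119 1.91421356237 -0.5
1.20710678119 -1.91421356237 0.5
1.20710678119 -1.91421356237 -0.5
-1.20710678119 1.91421356237 0.5
-1.20710678119 1.91421356237 -0.5
-1.20710678119 -1.91421356237 0.5
-1.20710678119 -1.91421356237 -0.5
1.91421356237 0.5 1.20710678119
1.91421356237 0.5 -1.20710678119
1.91421356237 -0.5 1.20710678119
1.91421356237 -0.5 -1.20710678119
-1.91421356237 0.5 1.20710678119
-1.91421356237 0.5 -1.20710678119
-1.91421356237 -0.5 1.20710678119
-1.91421356237 -0.5 -1.20710678119
1.91421356237 1.20710678119 0.5
1.91421356237 1.20710678119 -0.5
1.91421356237 -1.20710678119 0.5
1.91421356237 -1.20710678119 -0.5
-1.91421356237 1.20710678119 0.5
-1.91421356237 1.20710678119 -0.5
-1.91421356237 -1.20710678119 0.5
-1.91421356237 -1.20710678119 -0.5
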