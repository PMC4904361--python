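# truncated icosahedron | Archimedean | id 15
0 0.5 2.42705098312
0 0.5 -2.42705098312
0 -0.5 2.42705098312
0 -0.5 -2.42705098312
0.5 2.42705098312 0
0.5 -2.42705098312 0
-0.5 2.42705098312 0
-0.5 -2.42705098312 0
2.42705098312 0 0.5
2.42705098312 0 -0.5
-2.42705098312 0 0.5
-2.42705098312 0 -0.5
0.5 1.80901699437 1.61803398875
0.5 1.80901699437 -1.61803398875
0.5 -1.80901699437 1.61803398875
0.5 -1.80901699437 -1.61803398875
-0.5 1.80901699437 1.61803398875
-0.5 1.80901699437 -1.61803398875
-0.5 -1.80901699437 1.61803398875
-0.5 -1.80901699437 -1.61803398875
1.80901699437 1.61803398875 0.5
1.80901699437 1.61803398875 -0.5
1.80901699437 -1.61803398875 0.5
1.80901699437 -1.61803398875 -0.5
-1.80901699437 1.61803398875 0.5
-1.80901699437 1.61803398875 -0.5
-1.80901699437 -1.61803398875 0.5
-1.80901699437 -1.61803398875 -0.5
1.61803398875 0.5 1.80901699437
1.61803398875 0.5 -1.80901699437
1.61803398875 -0.5 1.80901699437
1.61803398875 -0.5 -1.80901699437
-1.61803398875 0.5 1.80901699437
-1.61803398875 0.5 -1.80901699437
-1.61803398875 -0.5 1.80901699437
-1.61803398875 -0.5 -1.80901699437
0.809016994375 1 2.11803398875
0.809016994375 1 -2.11803398875
0.809016994375 -1 2.11803398875
0.809016994375 -1 -2.11803398875
-0.809016994375 1 2.11803398875
-0.809016994375 1 -2.11803398875
-0.809016994375 -1 2.11803398875
-0.809016994375 -1 -2.11803398875
1 2.11803398875 0.809016994375
1 2.11803398875 -0.809016994375
1 -2.11803398875 0.809016994375
1 -2.11803398875 -0.809016994375
-1 2.11803398875 0.809016994375
-1 2.11803398875 -0.809016994375
-1 -2.11803398875 0.809016994375
-1 -2.11803398875 -0.809016994375
2.11803398875 0.809016994375 1
2.11803398875 0.809016994375 -1
2.11803398875 -0.809016994375 1
2.11803398875 -0.809016994375 -1
-2.11803398875 0.809016994375 1
-2.11803398875 0.809016994375 -1
-2.11803398875 -0.809016994375 1
-2.11803398875 -0.809016994375 -1
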