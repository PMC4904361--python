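# J80 parabidiminished rhombicosidodecahedron | Johnson | id 111
0.5 0.5 -2.11803398875
0.5 -0.5 -2.11803398875
-0.5 0.5 2.11803398875
-0.5 -0.5 2.11803398875
0.5 2.11803398875 0.5
0.5 2.11803398875 -0.5
0.5 -2.11803398875 0.5
0.5 -2.11803398875 -0.5
-0.5 2.11803398875 0.5
-0.5 2.11803398875 -0.5
-0.5 -2.11803398875 0.5
-0.5 -2.11803398875 -0.5
2.11803398875 0.5 0.5
2.11803398875 0.5 -0.5
2.11803398875 -0.5 0.5
2.11803398875 -0.5 -0.5
-2.11803398875 0.5 0.5
-2.11803398875 0.5 -0.5
-2.11803398875 -0.5 0.5
-2.11803398875 -0.5 -0.5
1.30901699437 0.809016994375 -1.61803398875
1.30901699437 -0.809016994375 -1.61803398875
-1.30901699437 0.809016994375 1.61803398875
-1.30901699437 -0.809016994375 1.61803398875
0.809016994375 1.61803398875 1.30901699437
0.809016994375 1.61803398875 -1.30901699437
0.809016994375 -1.61803398875 1.30901699437
0.809016994375 -1.61803398875 -1.30901699437
-0.809016994375 1.61803398875 1.30901699437
-0.809016994375 1.61803398875 -1.30901699437
-0.809016994375 -1.61803398875 1.30901699437
-0.809016994375 -1.61803398875 -1.30901699437
1.61803398875 1.30901699437 0.809016994375
1.61803398875 1.30901699437 -0.809016994375
1.61803398875 -1.30901699437 0.809016994375
1.61803398875 -1.30901699437 -0.809016994375
-1.61803398875 1.30901699437 0.809016994375
-1.61803398875 1.30901699437 -0.809016994375
-1.61803398875 -1.30901699437 0.809016994375
-1.61803398875 -1.30901699437 -0.809016994375
1.80901699437 0 -1.30901699437
-1.80901699437 0 1.30901699437
0 1.30901699437 1.80901699437
0 1.30901699437 -1.80901699437
0 -1.30901699437 1.80901699437
0 -1.30901699437 -1.80901699437
1.30901699437 1.80901699437 0
1.30901699437 -1.80901699437 0
-1.30901699437 1.80901699437 0
-1.30901699437 -1.80901699437 0
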