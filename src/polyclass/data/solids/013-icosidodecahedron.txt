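# icosidodecahedron | Archimedean | id 13
0 0 1.61803398875
0 0 -1.61803398875
0 1.61803398875 0
0 -1.61803398875 0
1.61803398875 0 0
-1.61803398875 0 0
0.5 0.809016994375 1.30901699437
0.5 0.809016994375 -1.30901699437
0.5 -0.809016994375 1.30901699437
0.5 -0.809016994375 -1.30901699437
-0.5 0.809016994375 1.30901699437
-0.5 0.809016994375 -1.30901699437
-0.5 -0.809016994375 1.30901699437
-0.5 -0.809016994375 -1.30901699437
0.809016994375 1.30901699437 0.5
0.809016994375 1.30901699437 -0.5
0.809016994375 -1.30901699437 0.5
0.809016994375 -1.30901699437 -0.5
-0.809016994375 1.30901699437 0.5
-0.809016994375 1.30901699437 -0.5
-0.809016994375 -1.30901699437 0.5
-0.809016994375 -1.30901699437 -0.5
1.30901699437 0.5 0.809016994375
1.30901699437 0.5 -0.809016994375
1.30901699437 -0.5 0.809016994375
1.30901699437 -0.5 -0.809016994375
-1.30901699437 0.5 0.809016994375
-1.30901699437 0.5 -0.809016994375
-1.30901699437 -0.5 0.809016994375
-1.30901699437 -0.5 -0.809016994375
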