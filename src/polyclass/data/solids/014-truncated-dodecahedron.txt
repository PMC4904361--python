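# truncated dodecahedron | Archimedean | id 14
-2.96059473233e-17 0.5 2.92705098312
-2.96059473233e-17 0.5 -2.92705098312
-2.96059473233e-17 -0.5 2.92705098312
-2.96059473233e-17 -0.5 -2.92705098312
0.5 2.92705098312 0
0.5 -2.92705098312 0
-0.5 2.92705098312 0
-0.5 -2.92705098312 0
2.92705098312 0 0.5
2.92705098312 0 -0.5
-2.92705098312 0 0.5
-2.92705098312 0 -0.5
0.5 1.30901699437 2.61803398875
0.5 1.30901699437 -2.61803398875
0.5 -1.30901699437 2.61803398875
0.5 -1.30901699437 -2.61803398875
-0.5 1.30901699437 2.61803398875
-0.5 1.30901699437 -2.61803398875
-0.5 -1.30901699437 2.61803398875
-0.5 -1.30901699437 -2.61803398875
1.30901699437 2.61803398875 0.5
1.30901699437 2.61803398875 -0.5
1.30901699437 -2.61803398875 0.5
1.30901699437 -2.61803398875 -0.5
-1.30901699437 2.61803398875 0.5
-1.30901699437 2.61803398875 -0.5
-1.30901699437 -2.61803398875 0.5
-1.30901699437 -2.61803398875 -0.5
2.61803398875 0.5 1.30901699437
2.61803398875 0.5 -1.30901699437
2.61803398875 -0.5 1.30901699437
2.61803398875 -0.5 -1.30901699437
-2.61803398875 0.5 1.30901699437
-2.61803398875 0.5 -1.30901699437
-2.61803398875 -0.5 1.30901699437
-2.61803398875 -0.5 -1.30901699437
1.30901699437 1.61803398875 2.11803398875
1.30901699437 1.61803398875 -2.11803398875
1.30901699437 -1.61803398875 2.11803398875
1.30901699437 -1.61803398875 -2.11803398875
-1.30901699437 1.61803398875 2.11803398875
-1.30901699437 1.61803398875 -2.11803398875
-1.30901699437 -1.61803398875 2.11803398875
-1.30901699437 -1.61803398875 -2.11803398875
1.61803398875 2.11803398875 1.30901699437
1.61803398875 2.11803398875 -1.30901699437
1.61803398875 -2.11803398875 1.30901699437
1.61803398875 -2.11803398875 -1.30901699437
-1.61803398875 2.11803398875 1.30901699437
-1.61803398875 2.11803398875 -1.30901699437
-1.61803398875 -2.11803398875 1.30901699437
-1.61803398875 -2.11803398875 -1.30901699437
2.11803398875 1.30901699437 1.61803398875
2.11803398875 1.30901699437 -1.61803398875
2.11803398875 -1.30901699437 1.61803398875
2.11803398875 -1.30901699437 -1.61803398875
-2.11803398875 1.30901699437 1.61803398875
-2.11803398875 1.30901699437 -1.61803398875
-2.11803398875 -1.30901699437 1.61803398875
-2.11803398875 -1.30901699437 -1.61803398875
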