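# J69 parabiaugmented truncated dodecahedron | Johnson | id 100
0 0.5 2.92705098312
0 0.5 -2.92705098312
0 -0.5 2.92705098312
0 -0.5 -2.92705098312
0.5 2.92705098312 -6.34413156929e-17
0.5 -2.92705098312 -6.34413156929e-17
-0.5 2.92705098312 -6.34413156929e-17
-0.5 -2.92705098312 -6.34413156929e-17
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
2.17082039325 0.5 -2.20344418537
2.17082039325 -0.5 -2.20344418537
1.36180339887 -0.809016994375 -2.70344418537
0.861803398875 -5.2087339482e-17 -3.01246117975
1.36180339887 0.809016994375 -2.70344418537
-1.36180339887 -0.809016994375 2.70344418537
-0.861803398875 2.69745300276e-17 3.01246117975
-1.36180339887 0.809016994375 2.70344418537
-2.17082039325 0.5 2.20344418537
-2.17082039325 -0.5 2.20344418537
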