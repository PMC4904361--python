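# J59 parabiaugmented dodecahedron | Johnson | id 90
-0.809016994375 -0.809016994375 -0.809016994375
-0.809016994375 -0.809016994375 0.809016994375
-0.809016994375 0.809016994375 -0.809016994375
-0.809016994375 0.809016994375 0.809016994375
0.809016994375 -0.809016994375 -0.809016994375
0.809016994375 -0.809016994375 0.809016994375
0.809016994375 0.809016994375 -0.809016994375
0.809016994375 0.809016994375 0.809016994375
2.0185873175e-17 0.5 1.30901699437
2.0185873175e-17 0.5 -1.30901699437
2.0185873175e-17 -0.5 1.30901699437
2.0185873175e-17 -0.5 -1.30901699437
0.5 1.30901699437 1.00929365875e-17
0.5 -1.30901699437 1.00929365875e-17
-0.5 1.30901699437 1.00929365875e-17
-0.5 -1.30901699437 1.00929365875e-17
1.30901699437 7.92472316245e-19 0.5
1.30901699437 7.92472316245e-19 -0.5
-1.30901699437 7.92472316245e-19 0.5
-1.30901699437 7.92472316245e-19 -0.5
-0.861803398875 7.92472316245e-19 -1.394427191
0.861803398875 -1.66419186412e-17 1.394427191
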