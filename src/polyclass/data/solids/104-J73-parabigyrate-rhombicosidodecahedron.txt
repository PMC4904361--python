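# J73 parabigyrate rhombicosidodecahedron | Johnson | id 104
0.361803398875 -1.42149249424e-16 2.20344418537
0.5 0.5 -2.11803398875
0.861803398875 -0.809016994375 1.894427191
0.5 -0.5 -2.11803398875
-0.5 0.5 2.11803398875
-0.361803398875 -1.42149249424e-16 -2.20344418537
-0.5 -0.5 2.11803398875
-0.861803398875 -0.809016994375 -1.894427191
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
0.861803398875 0.809016994375 1.894427191
1.30901699437 0.809016994375 -1.61803398875
1.67082039325 -0.5 1.394427191
1.30901699437 -0.809016994375 -1.61803398875
-1.30901699437 0.809016994375 1.61803398875
-0.861803398875 0.809016994375 -1.894427191
-1.30901699437 -0.809016994375 1.61803398875
-1.67082039325 -0.5 -1.394427191
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
1.67082039325 0.5 1.394427191
1.80901699437 2.96059473233e-17 -1.30901699437
-1.80901699437 2.96059473233e-17 1.30901699437
-1.67082039325 0.5 -1.394427191
0 1.30901699437 1.80901699437
0 1.30901699437 -1.80901699437
0 -1.30901699437 1.80901699437
0 -1.30901699437 -1.80901699437
1.30901699437 1.80901699437 0
1.30901699437 -1.80901699437 0
-1.30901699437 1.80901699437 0
-1.30901699437 -1.80901699437 0
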