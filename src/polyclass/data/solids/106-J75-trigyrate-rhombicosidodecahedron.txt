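# J75 trigyrate rhombicosidodecahedron | Johnson | id 106
0.361803398875 -1.75455940163e-16 2.20344418537
0.861803398875 0.809016994375 -1.894427191
0.861803398875 -0.809016994375 1.894427191
0.361803398875 1.68054453332e-16 -2.20344418537
-0.5 0.5 2.11803398875
-0.5 0.5 -2.11803398875
-0.5 -0.5 2.11803398875
-0.5 -0.5 -2.11803398875
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
-1.894427191 0.861803398875 0.809016994375
-2.20344418537 0.361803398875 1.63757896132e-16
-2.11803398875 -0.5 0.5
-2.11803398875 -0.5 -0.5
0.861803398875 0.809016994375 1.894427191
1.67082039325 0.5 -1.394427191
1.67082039325 -0.5 1.394427191
0.861803398875 -0.809016994375 -1.894427191
-1.30901699437 0.809016994375 1.61803398875
-1.30901699437 0.809016994375 -1.61803398875
-1.30901699437 -0.809016994375 1.61803398875
-1.30901699437 -0.809016994375 -1.61803398875
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
-1.394427191 1.67082039325 0.5
-1.894427191 0.861803398875 -0.809016994375
-1.61803398875 -1.30901699437 0.809016994375
-1.61803398875 -1.30901699437 -0.809016994375
1.67082039325 0.5 1.394427191
1.67082039325 -0.5 -1.394427191
-1.80901699437 -3.70074341542e-18 1.30901699437
-1.80901699437 -3.70074341542e-18 -1.30901699437
-2.96059473233e-17 1.30901699437 1.80901699437
-2.96059473233e-17 1.30901699437 -1.80901699437
-2.96059473233e-17 -1.30901699437 1.80901699437
-2.96059473233e-17 -1.30901699437 -1.80901699437
1.30901699437 1.80901699437 -2.77555756156e-18
1.30901699437 -1.80901699437 -2.77555756156e-18
-1.394427191 1.67082039325 -0.5
-1.30901699437 -1.80901699437 -2.77555756156e-18
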