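# truncated icosidodecahedron | Archimedean | id 17
0.5 0.5 3.7360679775
0.5 0.5 -3.7360679775
0.5 -0.5 3.7360679775
0.5 -0.5 -3.7360679775
-0.5 0.5 3.7360679775
-0.5 0.5 -3.7360679775
-0.5 -0.5 3.7360679775
-0.5 -0.5 -3.7360679775
0.5 3.7360679775 0.5
0.5 3.7360679775 -0.5
0.5 -3.7360679775 0.5
0.5 -3.7360679775 -0.5
-0.5 3.7360679775 0.5
-0.5 3.7360679775 -0.5
-0.5 -3.7360679775 0.5
-0.5 -3.7360679775 -0.5
3.7360679775 0.5 0.5
3.7360679775 0.5 -0.5
3.7360679775 -0.5 0.5
3.7360679775 -0.5 -0.5
-3.7360679775 0.5 0.5
-3.7360679775 0.5 -0.5
-3.7360679775 -0.5 0.5
-3.7360679775 -0.5 -0.5
1 1.30901699437 3.42705098312
1 1.30901699437 -3.42705098312
1 -1.30901699437 3.42705098312
1 -1.30901699437 -3.42705098312
-1 1.30901699437 3.42705098312
-1 1.30901699437 -3.42705098312
-1 -1.30901699437 3.42705098312
-1 -1.30901699437 -3.42705098312
1.30901699437 3.42705098312 1
1.30901699437 3.42705098312 -1
1.30901699437 -3.42705098312 1
1.30901699437 -3.42705098312 -1
-1.30901699437 3.42705098312 1
-1.30901699437 3.42705098312 -1
-1.30901699437 -3.42705098312 1
-1.30901699437 -3.42705098312 -1
3.42705098312 1 1.30901699437
3.42705098312 1 -1.30901699437
3.42705098312 -1 1.30901699437
3.42705098312 -1 -1.30901699437
-3.42705098312 1 1.30901699437
-3.42705098312 1 -1.30901699437
-3.42705098312 -1 1.30901699437
-3.42705098312 -1 -1.30901699437
0.5 2.11803398875 3.11803398875
0.5 2.11803398875 -3.11803398875
0.5 -2.11803398875 3.11803398875
0.5 -2.11803398875 -3.11803398875
-0.5 2.11803398875 3.11803398875
-0.5 2.11803398875 -3.11803398875
-0.5 -2.11803398875 3.11803398875
-0.5 -2.11803398875 -3.11803398875
2.11803398875 3.11803398875 0.5
2.11803398875 3.11803398875 -0.5
2.11803398875 -3.11803398875 0.5
2.11803398875 -3.11803398875 -0.5
-2.11803398875 3.11803398875 0.5
-2.11803398875 3.11803398875 -0.5
-2.11803398875 -3.11803398875 0.5
-2.11803398875 -3.11803398875 -0.5
3.11803398875 0.5 2.11803398875
3.11803398875 0.5 -2.11803398875
3.11803398875 -0.5 2.11803398875
3.11803398875 -0.5 -2.11803398875
-3.11803398875 0.5 2.11803398875
-3.11803398875 0.5 -2.11803398875
-3.11803398875 -0.5 2.11803398875
-3.11803398875 -0.5 -2.11803398875
1.80901699437 1.61803398875 2.92705098312
1.80901699437 1.61803398875 -2.92705098312
1.80901699437 -1.61803398875 2.92705098312
1.80901699437 -1.61803398875 -2.92705098312
-1.80901699437 1.61803398875 2.92705098312
-1.80901699437 1.61803398875 -2.92705098312
-1.80901699437 -1.61803398875 2.92705098312
-1.80901699437 -1.61803398875 -2.92705098312
1.61803398875 2.92705098312 1.80901699437
1.61803398875 2.92705098312 -1.80901699437
1.61803398875 -2.92705098312 1.80901699437
1.61803398875 -2.92705098312 -1.80901699437
-1.61803398875 2.92705098312 1.80901699437
-1.61803398875 2.92705098312 -1.80901699437
-1.61803398875 -2.92705098312 1.80901699437
-1.61803398875 -2.92705098312 -1.80901699437
2.92705098312 1.80901699437 1.61803398875
2.92705098312 1.80901699437 -1.61803398875
2.92705098312 -1.80901699437 1.61803398875
2.92705098312 -1.80901699437 -1.61803398875
-2.92705098312 1.80901699437 1.61803398875
-2.92705098312 1.80901699437 -1.61803398875
-2.92705098312 -1.80901699437 1.61803398875
-2.92705098312 -1.80901699437 -1.61803398875
1.30901699437 2.42705098312 2.61803398875
1.30901699437 2.42705098312 -2.61803398875
1.30901699437 -2.42705098312 2.61803398875
1.30901699437 -2.42705098312 -2.61803398875
-1.30901699437 2.42705098312 2.61803398875
-1.30901699437 2.42705098312 -2.61803398875
-1.30901699437 -2.42705098312 2.61803398875
-1.30901699437 -2.42705098312 -2.61803398875
2.42705098312 2.61803398875 1.30901699437
2.42705098312 2.61803398875 -1.30901699437
2.42705098312 -2.61803398875 1.30901699437
2.42705098312 -2.61803398875 -1.30901699437
-2.42705098312 2.61803398875 1.30901699437
-2.42705098312 2.61803398875 -1.30901699437
-2.42705098312 -2.61803398875 1.30901699437
-2.42705098312 -2.61803398875 -1.30901699437
2.61803398875 1.30901699437 2.42705098312
2.61803398875 1.30901699437 -2.42705098312
2.61803398875 -1.30901699437 2.42705098312
2.61803398875 -1.30901699437 -2.42705098312
-2.61803398875 1.30901699437 2.42705098312
-2.61803398875 1.30901699437 -2.42705098312
-2.61803398875 -1.30901699437 2.42705098312
-2.61803398875 -1.30901699437 -2.42705098312
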