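# J81 metabidiminished rhombicosidodecahedron | Johnson | id 112
-0.282917960675 0.5 2.11803398875
-0.282917960675 0.5 -2.11803398875
-0.282917960675 -0.5 2.11803398875
-0.282917960675 -0.5 -2.11803398875
0.717082039325 2.11803398875 0.5
0.717082039325 2.11803398875 -0.5
0.717082039325 -2.11803398875 0.5
0.717082039325 -2.11803398875 -0.5
-0.282917960675 2.11803398875 0.5
-0.282917960675 2.11803398875 -0.5
-0.282917960675 -2.11803398875 0.5
-0.282917960675 -2.11803398875 -0.5
2.33511602807 0.5 0.5
2.33511602807 0.5 -0.5
2.33511602807 -0.5 0.5
2.33511602807 -0.5 -0.5
-1.90095194942 0.5 0.5
-1.90095194942 0.5 -0.5
-1.90095194942 -0.5 0.5
-1.90095194942 -0.5 -0.5
-1.09193495505 0.809016994375 1.61803398875
-1.09193495505 0.809016994375 -1.61803398875
-1.09193495505 -0.809016994375 1.61803398875
-1.09193495505 -0.809016994375 -1.61803398875
1.0260990337 1.61803398875 1.30901699437
1.0260990337 1.61803398875 -1.30901699437
1.0260990337 -1.61803398875 1.30901699437
1.0260990337 -1.61803398875 -1.30901699437
-0.59193495505 1.61803398875 1.30901699437
-0.59193495505 1.61803398875 -1.30901699437
-0.59193495505 -1.61803398875 1.30901699437
-0.59193495505 -1.61803398875 -1.30901699437
1.83511602807 1.30901699437 0.809016994375
1.83511602807 1.30901699437 -0.809016994375
1.83511602807 -1.30901699437 0.809016994375
1.83511602807 -1.30901699437 -0.809016994375
-1.40095194942 1.30901699437 0.809016994375
-1.40095194942 1.30901699437 -0.809016994375
-1.40095194942 -1.30901699437 0.809016994375
-1.40095194942 -1.30901699437 -0.809016994375
-1.59193495505 0 1.30901699437
-1.59193495505 0 -1.30901699437
0.217082039325 1.30901699437 1.80901699437
0.217082039325 1.30901699437 -1.80901699437
0.217082039325 -1.30901699437 1.80901699437
0.217082039325 -1.30901699437 -1.80901699437
1.5260990337 1.80901699437 0
1.5260990337 -1.80901699437 0
-1.09193495505 1.80901699437 0
-1.09193495505 -1.80901699437 0
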