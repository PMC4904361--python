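# J83 tridiminished rhombicosidodecahedron | Johnson | id 114
-0.453934466292 0.620601132958 2.11803398875
-0.453934466292 0.620601132958 -2.11803398875
-0.453934466292 -0.379398867042 2.11803398875
-0.453934466292 -0.379398867042 -2.11803398875
0.546065533708 2.23863512171 0.5
0.546065533708 2.23863512171 -0.5
0.546065533708 -1.99743285579 0.5
0.546065533708 -1.99743285579 -0.5
-0.453934466292 2.23863512171 0.5
-0.453934466292 2.23863512171 -0.5
-0.453934466292 -1.99743285579 0.5
-0.453934466292 -1.99743285579 -0.5
2.16409952246 0.620601132958 0.5
2.16409952246 0.620601132958 -0.5
2.16409952246 -0.379398867042 0.5
2.16409952246 -0.379398867042 -0.5
-2.07196845504 -0.379398867042 0.5
-2.07196845504 -0.379398867042 -0.5
-1.26295146067 0.929618127333 1.61803398875
-1.26295146067 0.929618127333 -1.61803398875
-1.26295146067 -0.688415861417 1.61803398875
-1.26295146067 -0.688415861417 -1.61803398875
0.855082528083 1.73863512171 1.30901699437
0.855082528083 1.73863512171 -1.30901699437
0.855082528083 -1.49743285579 1.30901699437
0.855082528083 -1.49743285579 -1.30901699437
-0.762951460667 1.73863512171 1.30901699437
-0.762951460667 1.73863512171 -1.30901699437
-0.762951460667 -1.49743285579 1.30901699437
-0.762951460667 -1.49743285579 -1.30901699437
1.66409952246 1.42961812733 0.809016994375
1.66409952246 1.42961812733 -0.809016994375
1.66409952246 -1.18841586142 0.809016994375
1.66409952246 -1.18841586142 -0.809016994375
-1.57196845504 -1.18841586142 0.809016994375
-1.57196845504 -1.18841586142 -0.809016994375
-1.76295146067 0.120601132958 1.30901699437
-1.76295146067 0.120601132958 -1.30901699437
0.0460655337083 1.42961812733 1.80901699437
0.0460655337083 1.42961812733 -1.80901699437
0.0460655337083 -1.18841586142 1.80901699437
0.0460655337083 -1.18841586142 -1.80901699437
1.35508252808 1.92961812733 0
1.35508252808 -1.68841586142 0
-1.26295146067 -1.68841586142 0
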