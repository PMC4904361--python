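# J41 elongated pentagonal gyrocupolarotunda | Johnson | id 72
0.850650808352 6.34413156929e-17 1.34020277165
0.26286555606 0.809016994375 1.34020277165
-0.688190960236 0.5 1.34020277165
-0.688190960236 -0.5 1.34020277165
0.26286555606 -0.809016994375 1.34020277165
1.53884176859 0.5 0.814471659529
0.951056516295 1.30901699437 0.814471659529
1.08592204616e-16 1.61803398875 0.814471659529
-0.951056516295 1.30901699437 0.814471659529
-1.53884176859 0.5 0.814471659529
-1.53884176859 -0.5 0.814471659529
-0.951056516295 -1.30901699437 0.814471659529
-2.87711824431e-16 -1.61803398875 0.814471659529
0.951056516295 -1.30901699437 0.814471659529
1.53884176859 -0.5 0.814471659529
1.53884176859 0.5 -0.185528340471
0.951056516295 1.30901699437 -0.185528340471
1.08592204616e-16 1.61803398875 -0.185528340471
-0.951056516295 1.30901699437 -0.185528340471
-1.53884176859 0.5 -0.185528340471
-1.53884176859 -0.5 -0.185528340471
-0.951056516295 -1.30901699437 -0.185528340471
-2.87711824431e-16 -1.61803398875 -0.185528340471
0.951056516295 -1.30901699437 -0.185528340471
1.53884176859 -0.5 -0.185528340471
1.11351636441 -0.809016994375 -1.03617914882
-0.688190960236 0.5 -1.56191026094
0.850650808352 -2.63776137539e-17 -1.56191026094
0.26286555606 -0.809016994375 -1.56191026094
-0.425325404176 1.30901699437 -1.03617914882
0.26286555606 0.809016994375 -1.56191026094
-1.37638192047 1.15011135851e-16 -1.03617914882
-0.688190960236 -0.5 -1.56191026094
1.11351636441 0.809016994375 -1.03617914882
-0.425325404176 -1.30901699437 -1.03617914882
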