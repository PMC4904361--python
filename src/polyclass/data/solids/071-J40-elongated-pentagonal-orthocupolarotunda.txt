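# J40 elongated pentagonal orthocupolarotunda | Johnson | id 71
0.850650808352 7.93016446161e-17 1.34020277165
0.26286555606 0.809016994375 1.34020277165
-0.688190960236 0.5 1.34020277165
-0.688190960236 -0.5 1.34020277165
0.26286555606 -0.809016994375 1.34020277165
1.53884176859 0.5 0.814471659529
0.951056516295 1.30901699437 0.814471659529
1.37140796677e-16 1.61803398875 0.814471659529
-0.951056516295 1.30901699437 0.814471659529
-1.53884176859 0.5 0.814471659529
-1.53884176859 -0.5 0.814471659529
-0.951056516295 -1.30901699437 0.814471659529
-2.59163232369e-16 -1.61803398875 0.814471659529
0.951056516295 -1.30901699437 0.814471659529
1.53884176859 -0.5 0.814471659529
1.53884176859 0.5 -0.185528340471
0.951056516295 1.30901699437 -0.185528340471
1.37140796677e-16 1.61803398875 -0.185528340471
-0.951056516295 1.30901699437 -0.185528340471
-1.53884176859 0.5 -0.185528340471
-1.53884176859 -0.5 -0.185528340471
-0.951056516295 -1.30901699437 -0.185528340471
-2.59163232369e-16 -1.61803398875 -0.185528340471
0.951056516295 -1.30901699437 -0.185528340471
1.53884176859 -0.5 -0.185528340471
0.425325404176 -1.30901699437 -1.03617914882
-0.26286555606 0.809016994375 -1.56191026094
0.688190960236 -0.5 -1.56191026094
-0.26286555606 -0.809016994375 -1.56191026094
0.425325404176 1.30901699437 -1.03617914882
0.688190960236 0.5 -1.56191026094
-1.11351636441 0.809016994375 -1.03617914882
-0.850650808352 -1.21402858937e-16 -1.56191026094
1.37638192047 -7.77161187718e-17 -1.03617914882
-1.11351636441 -0.809016994375 -1.03617914882
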