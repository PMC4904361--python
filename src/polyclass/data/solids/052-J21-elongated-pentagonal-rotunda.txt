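# J21 elongated pentagonal rotunda | Johnson | id 52
0.425325404176 -1.30901699437 0.812812020215
-0.26286555606 0.809016994375 1.33854313233
0.688190960236 -0.5 1.33854313233
-0.26286555606 -0.809016994375 1.33854313233
0.425325404176 1.30901699437 0.812812020215
0.688190960236 0.5 1.33854313233
-1.11351636441 0.809016994375 0.812812020215
-0.850650808352 -9.33829445063e-17 1.33854313233
1.37638192047 -4.96962043407e-17 0.812812020215
-1.11351636441 -0.809016994375 0.812812020215
1.53884176859 0.5 -0.0378387881372
0.951056516295 1.30901699437 -0.0378387881372
1.36083441416e-16 1.61803398875 -0.0378387881372
-0.951056516295 1.30901699437 -0.0378387881372
-1.53884176859 0.5 -0.0378387881372
-1.53884176859 -0.5 -0.0378387881372
-0.951056516295 -1.30901699437 -0.0378387881372
-2.60220587631e-16 -1.61803398875 -0.0378387881372
0.951056516295 -1.30901699437 -0.0378387881372
1.53884176859 -0.5 -0.0378387881372
1.53884176859 0.5 -1.03783878814
0.951056516295 1.30901699437 -1.03783878814
1.36083441416e-16 1.61803398875 -1.03783878814
-0.951056516295 1.30901699437 -1.03783878814
-1.53884176859 0.5 -1.03783878814
-1.53884176859 -0.5 -1.03783878814
-0.951056516295 -1.30901699437 -1.03783878814
-2.60220587631e-16 -1.61803398875 -1.03783878814
0.951056516295 -1.30901699437 -1.03783878814
1.53884176859 -0.5 -1.03783878814
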