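# J39 elongated pentagonal gyrobicupola | Johnson | id 70
0.850650808352 4.4408920985e-17 1.02573111212
0.26286555606 0.809016994375 1.02573111212
-0.688190960236 0.5 1.02573111212
-0.688190960236 -0.5 1.02573111212
0.26286555606 -0.809016994375 1.02573111212
1.53884176859 0.5 0.5
0.951056516295 1.30901699437 0.5
1.65689388739e-16 1.61803398875 0.5
-0.951056516295 1.30901699437 0.5
-1.53884176859 0.5 0.5
-1.53884176859 -0.5 0.5
-0.951056516295 -1.30901699437 0.5
-2.30614640308e-16 -1.61803398875 0.5
0.951056516295 -1.30901699437 0.5
1.53884176859 -0.5 0.5
1.53884176859 0.5 -0.5
0.951056516295 1.30901699437 -0.5
1.65689388739e-16 1.61803398875 -0.5
-0.951056516295 1.30901699437 -0.5
-1.53884176859 0.5 -0.5
-1.53884176859 -0.5 -0.5
-0.951056516295 -1.30901699437 -0.5
-2.30614640308e-16 -1.61803398875 -0.5
0.951056516295 -1.30901699437 -0.5
1.53884176859 -0.5 -0.5
0.688190960236 0.5 -1.02573111212
-0.26286555606 0.809016994375 -1.02573111212
-0.850650808352 1.48583599949e-16 -1.02573111212
-0.26286555606 -0.809016994375 -1.02573111212
0.688190960236 -0.5 -1.02573111212
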