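# J43 elongated pentagonal gyrobirotunda | Johnson | id 74
0.425325404176 -1.30901699437 1.35065080835
-0.26286555606 0.809016994375 1.87638192047
0.688190960236 -0.5 1.87638192047
-0.26286555606 -0.809016994375 1.87638192047
0.425325404176 1.30901699437 1.35065080835
0.688190960236 0.5 1.87638192047
-1.11351636441 0.809016994375 1.35065080835
-0.850650808352 -1.00784431337e-16 1.87638192047
1.37638192047 -5.70976911716e-17 1.35065080835
-1.11351636441 -0.809016994375 1.35065080835
1.53884176859 0.5 0.5
0.951056516295 1.30901699437 0.5
8.51982194539e-17 1.61803398875 0.5
-0.951056516295 1.30901699437 0.5
-1.53884176859 0.5 0.5
-1.53884176859 -0.5 0.5
-0.951056516295 -1.30901699437 0.5
-3.11105809593e-16 -1.61803398875 0.5
0.951056516295 -1.30901699437 0.5
1.53884176859 -0.5 0.5
1.53884176859 0.5 -0.5
0.951056516295 1.30901699437 -0.5
8.51982194539e-17 1.61803398875 -0.5
-0.951056516295 1.30901699437 -0.5
-1.53884176859 0.5 -0.5
-1.53884176859 -0.5 -0.5
-0.951056516295 -1.30901699437 -0.5
-3.11105809593e-16 -1.61803398875 -0.5
0.951056516295 -1.30901699437 -0.5
1.53884176859 -0.5 -0.5
1.11351636441 -0.809016994375 -1.35065080835
-0.688190960236 0.5 -1.87638192047
0.850650808352 1.01011427695e-17 -1.87638192047
0.26286555606 -0.809016994375 -1.87638192047
-0.425325404176 1.30901699437 -1.35065080835
0.26286555606 0.809016994375 -1.87638192047
-1.37638192047 1.51489892375e-16 -1.35065080835
-0.688190960236 -0.5 -1.87638192047
1.11351636441 0.809016994375 -1.35065080835
-0.425325404176 -1.30901699437 -1.35065080835
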