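# J48 gyroelongated pentagonal birotunda | Johnson | id 79
0.425325404176 -1.30901699437 1.28184931028
-0.26286555606 0.809016994375 1.8075804224
0.688190960236 -0.5 1.8075804224
-0.26286555606 -0.809016994375 1.8075804224
0.425325404176 1.30901699437 1.28184931028
0.688190960236 0.5 1.8075804224
-1.11351636441 0.809016994375 1.28184931028
-0.850650808352 -9.5233316214e-17 1.8075804224
1.37638192047 -5.15465760484e-17 1.28184931028
-1.11351636441 -0.809016994375 1.28184931028
1.53884176859 0.5 0.43119850193
0.951056516295 1.30901699437 0.43119850193
8.79737770155e-17 1.61803398875 0.43119850193
-0.951056516295 1.30901699437 0.43119850193
-1.53884176859 0.5 0.43119850193
-1.53884176859 -0.5 0.43119850193
-0.951056516295 -1.30901699437 0.43119850193
-3.08330252031e-16 -1.61803398875 0.43119850193
0.951056516295 -1.30901699437 0.43119850193
1.53884176859 -0.5 0.43119850193
1.30901699437 0.951056516295 -0.43119850193
0.5 1.53884176859 -0.43119850193
-0.5 1.53884176859 -0.43119850193
-1.30901699437 0.951056516295 -0.43119850193
-1.61803398875 3.03623201863e-16 -0.43119850193
-1.30901699437 -0.951056516295 -0.43119850193
-0.5 -1.53884176859 -0.43119850193
0.5 -1.53884176859 -0.43119850193
1.30901699437 -0.951056516295 -0.43119850193
1.61803398875 -2.90832841707e-16 -0.43119850193
0.809016994375 -1.11351636441 -1.28184931028
-0.5 0.688190960236 -1.8075804224
0.809016994375 -0.26286555606 -1.8075804224
9.19292572354e-17 -0.850650808352 -1.8075804224
1.55323070613e-16 1.37638192047 -1.28184931028
0.5 0.688190960236 -1.8075804224
-1.30901699437 0.425325404176 -1.28184931028
-0.809016994375 -0.26286555606 -1.8075804224
1.30901699437 0.425325404176 -1.28184931028
-0.809016994375 -1.11351636441 -1.28184931028
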