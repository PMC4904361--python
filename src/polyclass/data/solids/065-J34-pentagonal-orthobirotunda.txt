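# J34 pentagonal orthobirotunda | Johnson | id 65
0.425325404176 -1.30901699437 0.850650808352
-0.26286555606 0.809016994375 1.37638192047
1.53884176859 0.5 3.70074341542e-17
-1.53884176859 -0.5 3.70074341542e-17
0.951056516295 -1.30901699437 -1.3343449651e-16
-3.05564431087e-17 1.61803398875 2.07449364818e-16
0.688190960236 -0.5 1.37638192047
-2.8655451538e-17 -1.61803398875 -1.3343449651e-16
-0.951056516295 1.30901699437 2.07449364818e-16
-0.26286555606 -0.809016994375 1.37638192047
0.425325404176 1.30901699437 0.850650808352
0.688190960236 0.5 1.37638192047
-1.11351636441 0.809016994375 0.850650808352
-0.850650808352 -1.08185918168e-16 1.37638192047
1.53884176859 -0.5 -7.79233452786e-17
0.951056516295 1.30901699437 1.51938213587e-16
1.37638192047 -6.44991780024e-17 0.850650808352
-0.951056516295 -1.30901699437 -7.79233452786e-17
-1.53884176859 0.5 1.51938213587e-16
-1.11351636441 -0.809016994375 0.850650808352
0.425325404176 -1.30901699437 -0.850650808352
-0.26286555606 0.809016994375 -1.37638192047
0.688190960236 -0.5 -1.37638192047
-0.26286555606 -0.809016994375 -1.37638192047
0.425325404176 1.30901699437 -0.850650808352
0.688190960236 0.5 -1.37638192047
-1.11351636441 0.809016994375 -0.850650808352
-0.850650808352 -1.08185918168e-16 -1.37638192047
1.37638192047 -6.44991780024e-17 -0.850650808352
-1.11351636441 -0.809016994375 -0.850650808352
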