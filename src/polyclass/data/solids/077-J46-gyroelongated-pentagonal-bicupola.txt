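# J46 gyroelongated pentagonal bicupola | Johnson | id 77
0.850650808352 4.81096644004e-17 0.956929614049
0.26286555606 0.809016994375 0.956929614049
-0.688190960236 0.5 0.956929614049
-0.688190960236 -0.5 0.956929614049
0.26286555606 -0.809016994375 0.956929614049
1.53884176859 0.5 0.43119850193
0.951056516295 1.30901699437 0.43119850193
1.61988645324e-16 1.61803398875 0.43119850193
-0.951056516295 1.30901699437 0.43119850193
-1.53884176859 0.5 0.43119850193
-1.53884176859 -0.5 0.43119850193
-0.951056516295 -1.30901699437 0.43119850193
-2.34315383723e-16 -1.61803398875 0.43119850193
0.951056516295 -1.30901699437 0.43119850193
1.53884176859 -0.5 0.43119850193
1.30901699437 0.951056516295 -0.43119850193
0.5 1.53884176859 -0.43119850193
-0.5 1.53884176859 -0.43119850193
-1.30901699437 0.951056516295 -0.43119850193
-1.61803398875 2.46261678924e-16 -0.43119850193
-1.30901699437 -0.951056516295 -0.43119850193
-0.5 -1.53884176859 -0.43119850193
0.5 -1.53884176859 -0.43119850193
1.30901699437 -0.951056516295 -0.43119850193
1.61803398875 -3.48194364646e-16 -0.43119850193
0.809016994375 0.26286555606 -0.956929614049
1.14999977544e-16 0.850650808352 -0.956929614049
-0.809016994375 0.26286555606 -0.956929614049
-0.5 -0.688190960236 -0.956929614049
0.5 -0.688190960236 -0.956929614049
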