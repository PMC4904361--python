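# J32 pentagonal orthocupolarotunda | Johnson | id 63
0.850650808352 6.2172489379e-17 0.86599143546
0.26286555606 0.809016994375 0.86599143546
-0.688190960236 0.5 0.86599143546
-0.688190960236 -0.5 0.86599143546
0.26286555606 -0.809016994375 0.86599143546
0.425325404176 -1.30901699437 -0.510390485011
-0.26286555606 0.809016994375 -1.03612159713
1.53884176859 0.5 0.340260323341
-1.53884176859 -0.5 0.340260323341
0.951056516295 -1.30901699437 0.340260323341
-9.83227998233e-18 1.61803398875 0.340260323341
0.688190960236 -0.5 -1.03612159713
-7.93128841167e-18 -1.61803398875 0.340260323341
-0.951056516295 1.30901699437 0.340260323341
-0.26286555606 -0.809016994375 -1.03612159713
0.425325404176 1.30901699437 -0.510390485011
0.688190960236 0.5 -1.03612159713
-1.11351636441 0.809016994375 -0.510390485011
-0.850650808352 -1.38532014174e-16 -1.03612159713
1.53884176859 -0.5 0.340260323341
0.951056516295 1.30901699437 0.340260323341
1.37638192047 -9.48452740088e-17 -0.510390485011
-0.951056516295 -1.30901699437 0.340260323341
-1.53884176859 0.5 0.340260323341
-1.11351636441 -0.809016994375 -0.510390485011
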