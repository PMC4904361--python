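# J33 pentagonal gyrocupolarotunda | Johnson | id 64
0.850650808352 3.5527136788e-17 0.86599143546
0.26286555606 0.809016994375 0.86599143546
-0.688190960236 0.5 0.86599143546
-0.688190960236 -0.5 0.86599143546
0.26286555606 -0.809016994375 0.86599143546
1.53884176859 0.5 0.340260323341
-1.53884176859 -0.5 0.340260323341
0.951056516295 -1.30901699437 0.340260323341
-5.86820930658e-17 1.61803398875 0.340260323341
-5.67811014952e-17 -1.61803398875 0.340260323341
-0.951056516295 1.30901699437 0.340260323341
1.53884176859 -0.5 0.340260323341
0.951056516295 1.30901699437 0.340260323341
-0.951056516295 -1.30901699437 0.340260323341
-1.53884176859 0.5 0.340260323341
1.11351636441 -0.809016994375 -0.510390485011
-0.688190960236 0.5 -1.03612159713
0.850650808352 -5.42917926588e-17 -1.03612159713
0.26286555606 -0.809016994375 -1.03612159713
-0.425325404176 1.30901699437 -0.510390485011
0.26286555606 0.809016994375 -1.03612159713
-1.37638192047 8.70969569463e-17 -0.510390485011
-0.688190960236 -0.5 -1.03612159713
1.11351636441 0.809016994375 -0.510390485011
-0.425325404176 -1.30901699437 -0.510390485011
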