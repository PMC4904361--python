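# J6 pentagonal rotunda | Johnson | id 37
0.425325404176 -1.30901699437 0.293892626146
-0.26286555606 0.809016994375 0.819623738265
1.53884176859 0.5 -0.556758182206
-1.53884176859 -0.5 -0.556758182206
0.951056516295 -1.30901699437 -0.556758182206
-1.20527260316e-17 1.61803398875 -0.556758182206
0.688190960236 -0.5 0.819623738265
-1.01517344609e-17 -1.61803398875 -0.556758182206
-0.951056516295 1.30901699437 -0.556758182206
-0.26286555606 -0.809016994375 0.819623738265
0.425325404176 1.30901699437 0.293892626146
0.688190960236 0.5 0.819623738265
-1.11351636441 0.809016994375 0.293892626146
-0.850650808352 -1.2298889183e-16 0.819623738265
1.53884176859 -0.5 -0.556758182206
0.951056516295 1.30901699437 -0.556758182206
1.37638192047 -7.93021516641e-17 0.293892626146
-0.951056516295 -1.30901699437 -0.556758182206
-1.53884176859 0.5 -0.556758182206
-1.11351636441 -0.809016994375 0.293892626146
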