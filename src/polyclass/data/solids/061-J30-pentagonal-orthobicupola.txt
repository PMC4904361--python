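# J30 pentagonal orthobicupola | Johnson | id 61
1.53884176859 0.5 1.11022302463e-17
0.951056516295 1.30901699437 1.11022302463e-17
1.54587158493e-16 1.61803398875 1.11022302463e-17
-0.951056516295 1.30901699437 1.11022302463e-17
-1.53884176859 0.5 1.11022302463e-17
-1.53884176859 -0.5 1.11022302463e-17
-0.951056516295 -1.30901699437 1.11022302463e-17
-2.41716870554e-16 -1.61803398875 1.11022302463e-17
0.951056516295 -1.30901699437 1.11022302463e-17
1.53884176859 -0.5 1.11022302463e-17
0.850650808352 1.66533453694e-17 0.525731112119
0.26286555606 0.809016994375 0.525731112119
-0.688190960236 0.5 0.525731112119
-0.688190960236 -0.5 0.525731112119
0.26286555606 -0.809016994375 0.525731112119
0.850650808352 1.66533453694e-17 -0.525731112119
0.26286555606 0.809016994375 -0.525731112119
-0.688190960236 0.5 -0.525731112119
-0.688190960236 -0.5 -0.525731112119
0.26286555606 -0.809016994375 -0.525731112119
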