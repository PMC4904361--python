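# J47 gyroelongated pentagonal cupolarotunda | Johnson | id 78
0.850650808352 6.97854472622e-17 1.26157248814
0.26286555606 0.809016994375 1.26157248814
-0.688190960236 0.5 1.26157248814
-0.688190960236 -0.5 1.26157248814
0.26286555606 -0.809016994375 1.26157248814
1.53884176859 0.5 0.73584137602
0.951056516295 1.30901699437 0.73584137602
1.117642704e-16 1.61803398875 0.73584137602
-0.951056516295 1.30901699437 0.73584137602
-1.53884176859 0.5 0.73584137602
-1.53884176859 -0.5 0.73584137602
-0.951056516295 -1.30901699437 0.73584137602
-2.84539758647e-16 -1.61803398875 0.73584137602
0.951056516295 -1.30901699437 0.73584137602
1.53884176859 -0.5 0.73584137602
1.30901699437 0.951056516295 -0.126555627839
0.5 1.53884176859 -0.126555627839
-0.5 1.53884176859 -0.126555627839
-1.30901699437 0.951056516295 -0.126555627839
-1.61803398875 2.67937461786e-16 -0.126555627839
-1.30901699437 -0.951056516295 -0.126555627839
-0.5 -1.53884176859 -0.126555627839
0.5 -1.53884176859 -0.126555627839
1.30901699437 -0.951056516295 -0.126555627839
1.61803398875 -3.26518581785e-16 -0.126555627839
0.809016994375 -1.11351636441 -0.977206436191
-0.5 0.688190960236 -1.50293754831
0.809016994375 -0.26286555606 -1.50293754831
1.1571975062e-16 -0.850650808352 -1.50293754831
1.79113563997e-16 1.37638192047 -0.977206436191
0.5 0.688190960236 -1.50293754831
-1.30901699437 0.425325404176 -0.977206436191
-0.809016994375 -0.26286555606 -1.50293754831
1.30901699437 0.425325404176 -0.977206436191
-0.809016994375 -1.11351636441 -0.977206436191
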