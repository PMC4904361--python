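# J5 pentagonal cupola | Johnson | id 36
1.53884176859 0.5 -0.17524370404
0.951056516295 1.30901699437 -0.17524370404
1.58287901908e-16 1.61803398875 -0.17524370404
-0.951056516295 1.30901699437 -0.17524370404
-1.53884176859 0.5 -0.17524370404
-1.53884176859 -0.5 -0.17524370404
-0.951056516295 -1.30901699437 -0.17524370404
-2.38016127138e-16 -1.61803398875 -0.17524370404
0.951056516295 -1.30901699437 -0.17524370404
1.53884176859 -0.5 -0.17524370404
0.850650808352 2.22044604925e-17 0.350487408079
0.26286555606 0.809016994375 0.350487408079
-0.688190960236 0.5 0.350487408079
-0.688190960236 -0.5 0.350487408079
0.26286555606 -0.809016994375 0.350487408079
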