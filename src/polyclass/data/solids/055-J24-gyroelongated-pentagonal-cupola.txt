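# J24 gyroelongated pentagonal cupola | Johnson | id 55
0.850650808352 5.58201900484e-17 0.765543691239
0.26286555606 0.809016994375 0.765543691239
-0.688190960236 0.5 0.765543691239
-0.688190960236 -0.5 0.765543691239
0.26286555606 -0.809016994375 0.765543691239
1.53884176859 0.5 0.23981257912
0.951056516295 1.30901699437 0.23981257912
1.61248496641e-16 1.61803398875 0.23981257912
-0.951056516295 1.30901699437 0.23981257912
-1.53884176859 0.5 0.23981257912
-1.53884176859 -0.5 0.23981257912
-0.951056516295 -1.30901699437 0.23981257912
-2.35055532406e-16 -1.61803398875 0.23981257912
0.951056516295 -1.30901699437 0.23981257912
1.53884176859 -0.5 0.23981257912
1.30901699437 0.951056516295 -0.62258442474
0.5 1.53884176859 -0.62258442474
-0.5 1.53884176859 -0.62258442474
-1.30901699437 0.951056516295 -0.62258442474
-1.61803398875 2.53972204572e-16 -0.62258442474
-1.30901699437 -0.951056516295 -0.62258442474
-0.5 -1.53884176859 -0.62258442474
0.5 -1.53884176859 -0.62258442474
1.30901699437 -0.951056516295 -0.62258442474
1.61803398875 -3.40483838998e-16 -0.62258442474
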