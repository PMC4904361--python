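# J25 gyroelongated pentagonal rotunda | Johnson | id 56
0.425325404176 -1.30901699437 0.766944354835
-0.26286555606 0.809016994375 1.29267546695
0.688190960236 -0.5 1.29267546695
-0.26286555606 -0.809016994375 1.29267546695
0.425325404176 1.30901699437 0.766944354835
0.688190960236 0.5 1.29267546695
-1.11351636441 0.809016994375 0.766944354835
-0.850650808352 -9.49757838664e-17 1.29267546695
1.37638192047 -5.12890437008e-17 0.766944354835
-1.11351636441 -0.809016994375 0.766944354835
1.53884176859 0.5 -0.0837064535174
0.951056516295 1.30901699437 -0.0837064535174
1.21280467754e-16 1.61803398875 -0.0837064535174
-0.951056516295 1.30901699437 -0.0837064535174
-1.53884176859 0.5 -0.0837064535174
-1.53884176859 -0.5 -0.0837064535174
-0.951056516295 -1.30901699437 -0.0837064535174
-2.75023561293e-16 -1.61803398875 -0.0837064535174
0.951056516295 -1.30901699437 -0.0837064535174
1.53884176859 -0.5 -0.0837064535174
1.30901699437 0.951056516295 -0.946103457377
0.5 1.53884176859 -0.946103457377
-0.5 1.53884176859 -0.946103457377
-1.30901699437 0.951056516295 -0.946103457377
-1.61803398875 3.0388073421e-16 -0.946103457377
-1.30901699437 -0.951056516295 -0.946103457377
-0.5 -1.53884176859 -0.946103457377
0.5 -1.53884176859 -0.946103457377
1.30901699437 -0.951056516295 -0.946103457377
1.61803398875 -2.9057530936e-16 -0.946103457377
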