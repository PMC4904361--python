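# J1 square pyramid | Johnson | id 32
0.707106781187 -2.22044604925e-17 -0.141421356237
6.92764844988e-17 0.707106781187 -0.141421356237
-0.707106781187 6.4391145131e-17 -0.141421356237
-1.03914726748e-16 -0.707106781187 -0.141421356237
2.59786816871e-17 -2.22044604925e-17 0.565685424949
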