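# J10 gyroelongated square pyramid | Johnson | id 41
0.707106781187 -1.23358113847e-17 0.295164319981
6.79694255812e-17 0.707106781187 0.295164319981
-0.707106781187 7.42597942388e-17 0.295164319981
-1.05221785666e-16 -0.707106781187 0.295164319981
0.5 0.5 -0.545732095273
-0.5 0.5 -0.545732095273
-0.5 -0.5 -0.545732095273
0.5 -0.5 -0.545732095273
2.46716227694e-17 -1.23358113847e-17 1.00227110117
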