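# J11 gyroelongated pentagonal pyramid | Johnson | id 42
0.850650808352 0 0.338865720876
0.26286555606 0.809016994375 0.338865720876
-0.688190960236 0.5 0.338865720876
-0.688190960236 -0.5 0.338865720876
0.26286555606 -0.809016994375 0.338865720876
0.688190960236 0.5 -0.511785087476
-0.26286555606 0.809016994375 -0.511785087476
-0.850650808352 1.04174678964e-16 -0.511785087476
-0.26286555606 -0.809016994375 -0.511785087476
0.688190960236 -0.5 -0.511785087476
2.0185873175e-17 0 0.864596832996
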