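# J8 elongated square pyramid | Johnson | id 39
0.707106781187 -2.46716227694e-17 0.365877024313
7.00662151338e-17 0.707106781187 0.365877024313
-0.707106781187 6.19239828541e-17 0.365877024313
-1.03124996113e-16 -0.707106781187 0.365877024313
0.707106781187 -2.46716227694e-17 -0.634122975687
7.00662151338e-17 0.707106781187 -0.634122975687
-0.707106781187 6.19239828541e-17 -0.634122975687
-1.03124996113e-16 -0.707106781187 -0.634122975687
2.6768412322e-17 -2.46716227694e-17 1.0729838055
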