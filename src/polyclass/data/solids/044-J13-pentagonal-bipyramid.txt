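# J13 pentagonal bipyramid | Johnson | id 44
0.850650808352 -1.58603289232e-17 0
0.26286555606 0.809016994375 0
-0.688190960236 0.5 0
-0.688190960236 -0.5 0
0.26286555606 -0.809016994375 0
3.17206578464e-17 -1.58603289232e-17 0.525731112119
3.17206578464e-17 -1.58603289232e-17 -0.525731112119
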