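# icosahedron | Platonic | id 5
0 0.5 0.809016994375
0 0.5 -0.809016994375
0 -0.5 0.809016994375
0 -0.5 -0.809016994375
0.5 0.809016994375 0
0.5 -0.809016994375 0
-0.5 0.809016994375 0
-0.5 -0.809016994375 0
0.809016994375 0 0.5
0.809016994375 0 -0.5
-0.809016994375 0 0.5
-0.809016994375 0 -0.5
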