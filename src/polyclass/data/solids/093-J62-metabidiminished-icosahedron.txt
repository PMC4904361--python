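# J62 metabidiminished icosahedron | Johnson | id 93
0 -0.4 0.809016994375
0 -0.4 -0.809016994375
0.5 0.909016994375 0
0.5 -0.709016994375 0
-0.5 0.909016994375 0
-0.5 -0.709016994375 0
0.809016994375 0.1 0.5
0.809016994375 0.1 -0.5
-0.809016994375 0.1 0.5
-0.809016994375 0.1 -0.5
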