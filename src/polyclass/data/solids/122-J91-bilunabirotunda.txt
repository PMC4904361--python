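# J91 bilunabirotunda | Johnson | id 122
0.809016994375 0.5 0.5
0.809016994375 0.5 -0.5
0.809016994375 -0.5 0.5
0.809016994375 -0.5 -0.5
-0.809016994375 0.5 0.5
-0.809016994375 0.5 -0.5
-0.809016994375 -0.5 0.5
-0.809016994375 -0.5 -0.5
0.5 0 1.30901699437
0.5 0 -1.30901699437
-0.5 0 1.30901699437
-0.5 0 -1.30901699437
0 0.809016994375 0
0 -0.809016994375 0
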