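# J16 elongated pentagonal bipyramid | Johnson | id 47
0.850650808352 -9.25185853854e-18 0.5
0.26286555606 0.809016994375 0.5
-0.688190960236 0.5 0.5
-0.688190960236 -0.5 0.5
0.26286555606 -0.809016994375 0.5
0.850650808352 -9.25185853854e-18 -0.5
0.26286555606 0.809016994375 -0.5
-0.688190960236 0.5 -0.5
-0.688190960236 -0.5 -0.5
0.26286555606 -0.809016994375 -0.5
3.70074341542e-17 -9.25185853854e-18 1.02573111212
3.70074341542e-17 -9.25185853854e-18 -1.02573111212
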