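# J9 elongated pentagonal pyramid | Johnson | id 40
0.850650808352 -1.00929365875e-17 0.40675171708
0.26286555606 0.809016994375 0.40675171708
-0.688190960236 0.5 0.40675171708
-0.688190960236 -0.5 0.40675171708
0.26286555606 -0.809016994375 0.40675171708
0.850650808352 -1.00929365875e-17 -0.59324828292
0.26286555606 0.809016994375 -0.59324828292
-0.688190960236 0.5 -0.59324828292
-0.688190960236 -0.5 -0.59324828292
0.26286555606 -0.809016994375 -0.59324828292
4.037174635e-17 -1.00929365875e-17 0.932482829199
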