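# J2 pentagonal pyramid | Johnson | id 33
0.850650808352 -1.85037170771e-17 -0.0876218520199
0.26286555606 0.809016994375 -0.0876218520199
-0.688190960236 0.5 -0.0876218520199
-0.688190960236 -0.5 -0.0876218520199
0.26286555606 -0.809016994375 -0.0876218520199
3.70074341542e-17 -1.85037170771e-17 0.438109260099
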