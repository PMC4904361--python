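# J84 snub disphenoid | Johnson | id 115
0.644584273224 0.205561565853 0
-0.644584273224 0.205561565853 0
0 -0.205561565853 0.644584273224
0 -0.205561565853 -0.644584273224
0.5 -0.783930924233 0
-0.5 -0.783930924233 0
0 0.783930924233 0.5
0 0.783930924233 -0.5
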