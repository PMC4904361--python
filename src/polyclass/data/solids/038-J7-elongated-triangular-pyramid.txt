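# J7 elongated triangular pyramid | Johnson | id 38
0.57735026919 -6.34413156929e-17 0.311929059867
-0.288675134595 0.5 0.311929059867
-0.288675134595 -0.5 0.311929059867
0.57735026919 -6.34413156929e-17 -0.688070940133
-0.288675134595 0.5 -0.688070940133
-0.288675134595 -0.5 -0.688070940133
3.9650822308e-17 -6.34413156929e-17 1.1284256408
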