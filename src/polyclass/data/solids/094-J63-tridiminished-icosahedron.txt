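# J63 tridiminished icosahedron | Johnson | id 94
0.0555555555556 -0.478779666042 0.809016994375
0.0555555555556 -0.478779666042 -0.809016994375
0.555555555556 0.830237328333 0
-0.444444444444 0.830237328333 0
-0.444444444444 -0.787796660417 0
0.864572549931 0.0212203339583 0.5
0.864572549931 0.0212203339583 -0.5
-0.753461438819 0.0212203339583 0.5
-0.753461438819 0.0212203339583 -0.5
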