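# J29 square gyrobicupola | Johnson | id 60
1.20710678119 0.5 1.38777878078e-17
0.5 1.20710678119 1.38777878078e-17
-0.5 1.20710678119 1.38777878078e-17
-1.20710678119 0.5 1.38777878078e-17
-1.20710678119 -0.5 1.38777878078e-17
-0.5 -1.20710678119 1.38777878078e-17
0.5 -1.20710678119 1.38777878078e-17
1.20710678119 -0.5 1.38777878078e-17
0.707106781187 2.42861286637e-17 0.707106781187
1.05747847947e-16 0.707106781187 0.707106781187
-0.707106781187 1.10881734287e-16 0.707106781187
-6.74433633002e-17 -0.707106781187 0.707106781187
0.5 0.5 -0.707106781187
-0.5 0.5 -0.707106781187
-0.5 -0.5 -0.707106781187
0.5 -0.5 -0.707106781187
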