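# J28 square orthobicupola | Johnson | id 59
1.20710678119 0.5 1.38777878078e-17
0.5 1.20710678119 1.38777878078e-17
-0.5 1.20710678119 1.38777878078e-17
-1.20710678119 0.5 1.38777878078e-17
-1.20710678119 -0.5 1.38777878078e-17
-0.5 -1.20710678119 1.38777878078e-17
0.5 -1.20710678119 1.38777878078e-17
1.20710678119 -0.5 1.38777878078e-17
0.707106781187 2.08166817117e-17 0.707106781187
9.99883981663e-17 0.707106781187 0.707106781187
-0.707106781187 1.07412287335e-16 0.707106781187
-7.32028130808e-17 -0.707106781187 0.707106781187
0.707106781187 2.08166817117e-17 -0.707106781187
9.99883981663e-17 0.707106781187 -0.707106781187
-0.707106781187 1.07412287335e-16 -0.707106781187
-7.32028130808e-17 -0.707106781187 -0.707106781187
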