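# J15 elongated square bipyramid | Johnson | id 46
0.707106781187 -2.22044604925e-17 0.5
6.73893739016e-17 0.707106781187 0.5
-0.707106781187 6.4391145131e-17 0.5
-1.05801837346e-16 -0.707106781187 0.5
0.707106781187 -2.22044604925e-17 -0.5
6.73893739016e-17 0.707106781187 -0.5
-0.707106781187 6.4391145131e-17 -0.5
-1.05801837346e-16 -0.707106781187 -0.5
2.40915710898e-17 -2.22044604925e-17 1.20710678119
2.40915710898e-17 -2.22044604925e-17 -1.20710678119
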