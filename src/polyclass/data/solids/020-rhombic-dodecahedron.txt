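# rhombic dodecahedron | Catalan | id 20
0.707106781187 0.707106781187 -0.707106781187
0.707106781187 -0.707106781187 -0.707106781187
-0.707106781187 0.707106781187 -0.707106781187
-0.707106781187 -0.707106781187 -0.707106781187
0.707106781187 0.707106781187 0.707106781187
-0.707106781187 0.707106781187 0.707106781187
0.707106781187 -0.707106781187 0.707106781187
-0.707106781187 -0.707106781187 0.707106781187
1.41421356237 0 1.58603289232e-17
1.58603289232e-17 -0 -1.41421356237
-1.41421356237 -0 1.58603289232e-17
1.58603289232e-17 1.41421356237 1.58603289232e-17
1.58603289232e-17 0 1.41421356237
1.58603289232e-17 -1.41421356237 1.58603289232e-17
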