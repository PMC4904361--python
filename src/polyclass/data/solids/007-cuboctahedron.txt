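# cuboctahedron | Archimedean | id 7
0.707106781187 0.707106781187 0
0.707106781187 -0.707106781187 0
-0.707106781187 0.707106781187 0
-0.707106781187 -0.707106781187 0
0.707106781187 0 0.707106781187
0.707106781187 0 -0.707106781187
-0.707106781187 0 0.707106781187
-0.707106781187 0 -0.707106781187
0 0.707106781187 0.707106781187
0 0.707106781187 -0.707106781187
0 -0.707106781187 0.707106781187
0 -0.707106781187 -0.707106781187
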