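# truncated octahedron | Archimedean | id 9
0 0.707106781187 1.41421356237
0 0.707106781187 -1.41421356237
0 -0.707106781187 1.41421356237
0 -0.707106781187 -1.41421356237
0 1.41421356237 0.707106781187
0 1.41421356237 -0.707106781187
0 -1.41421356237 0.707106781187
0 -1.41421356237 -0.707106781187
0.707106781187 0 1.41421356237
0.707106781187 0 -1.41421356237
-0.707106781187 0 1.41421356237
-0.707106781187 0 -1.41421356237
0.707106781187 1.41421356237 0
0.707106781187 -1.41421356237 0
-0.707106781187 1.41421356237 0
-0.707106781187 -1.41421356237 0
1.41421356237 0 0.707106781187
1.41421356237 0 -0.707106781187
-1.41421356237 0 0.707106781187
-1.41421356237 0 -0.707106781187
1.41421356237 0.707106781187 0
1.41421356237 -0.707106781187 0
-1.41421356237 0.707106781187 0
-1.41421356237 -0.707106781187 0
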