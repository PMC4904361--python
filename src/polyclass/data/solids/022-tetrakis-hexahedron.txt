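# tetrakis hexahedron | Catalan | id 22
-7.93016446161e-18 -0 -0.707106781187
-7.93016446161e-18 0.707106781187 -7.93016446161e-18
-7.93016446161e-18 -0.707106781187 -7.93016446161e-18
0.471404520791 0.471404520791 0.471404520791
-0.471404520791 0.471404520791 0.471404520791
-7.93016446161e-18 0 0.707106781187
-0.471404520791 -0.471404520791 0.471404520791
0.471404520791 -0.471404520791 0.471404520791
-0.471404520791 0.471404520791 -0.471404520791
-0.471404520791 -0.471404520791 -0.471404520791
-0.707106781187 -0 -7.93016446161e-18
0.471404520791 0.471404520791 -0.471404520791
0.471404520791 -0.471404520791 -0.471404520791
0.707106781187 0 -7.93016446161e-18
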