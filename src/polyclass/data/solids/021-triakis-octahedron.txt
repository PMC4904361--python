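# triakis octahedron | Catalan | id 21
0.343145750508 0.343145750508 0.343145750508
-0.343145750508 -0.343145750508 0.343145750508
-0.343145750508 -0.343145750508 -0.343145750508
-0.343145750508 0.343145750508 0.343145750508
0.343145750508 -0.343145750508 -0.343145750508
0.343145750508 -0.343145750508 0.343145750508
0.343145750508 0.343145750508 -0.343145750508
-0.343145750508 0.343145750508 -0.343145750508
0 -7.93016446161e-18 0.828427124746
-0 -0.828427124746 -1.44997278053e-17
-0 -7.93016446161e-18 -0.828427124746
0.828427124746 -7.93016446161e-18 -1.44997278053e-17
-0.828427124746 -7.93016446161e-18 -1.44997278053e-17
-0 0.828427124746 7.74741590064e-17
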