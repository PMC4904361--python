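# J57 triaugmented hexagonal prism | Johnson | id 88
1 -8.881784197e-17 0.5
0.5 0.866025403784 0.5
-0.5 0.866025403784 0.5
-1 3.36468379447e-17 0.5
-0.5 -0.866025403784 0.5
0.5 -0.866025403784 0.5
1 -8.881784197e-17 -0.5
0.5 0.866025403784 -0.5
-0.5 0.866025403784 -0.5
-1 3.36468379447e-17 -0.5
-0.5 -0.866025403784 -0.5
0.5 -0.866025403784 -0.5
1.3623724357 0.786566092485 -7.36525809235e-18
-1.3623724357 0.786566092485 -7.36525809235e-18
-1.55431223448e-16 -1.57313218497 1.13311662959e-18
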