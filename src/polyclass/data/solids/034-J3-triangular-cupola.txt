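# J3 triangular cupola | Johnson | id 34
0.866025403784 0.5 -0.272165526976
6.74002456497e-17 1 -0.272165526976
-0.866025403784 0.5 -0.272165526976
-0.866025403784 -0.5 -0.272165526976
-1.7752911418e-16 -1 -0.272165526976
0.866025403784 -0.5 -0.272165526976
0.57735026919 -1.48029736617e-16 0.544331053952
-0.288675134595 0.5 0.544331053952
-0.288675134595 -0.5 0.544331053952
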