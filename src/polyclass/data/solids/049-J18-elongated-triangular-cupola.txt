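# J18 elongated triangular cupola | Johnson | id 49
0.57735026919 -1.33226762955e-16 1.05319726474
-0.288675134595 0.5 1.05319726474
-0.288675134595 -0.5 1.05319726474
0.866025403784 0.5 0.236700683814
5.38308531265e-17 1 0.236700683814
-0.866025403784 0.5 0.236700683814
-0.866025403784 -0.5 0.236700683814
-1.91098506703e-16 -1 0.236700683814
0.866025403784 -0.5 0.236700683814
0.866025403784 0.5 -0.763299316186
5.38308531265e-17 1 -0.763299316186
-0.866025403784 0.5 -0.763299316186
-0.866025403784 -0.5 -0.763299316186
-1.91098506703e-16 -1 -0.763299316186
0.866025403784 -0.5 -0.763299316186
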