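# J55 parabiaugmented hexagonal prism | Johnson | id 86
1 -9.51619735393e-17 0.5
0.5 0.866025403784 0.5
-0.5 0.866025403784 0.5
-1 2.73027063754e-17 0.5
-0.5 -0.866025403784 0.5
0.5 -0.866025403784 0.5
1 -9.51619735393e-17 -0.5
0.5 0.866025403784 -0.5
-0.5 0.866025403784 -0.5
-1 2.73027063754e-17 -0.5
-0.5 -0.866025403784 -0.5
0.5 -0.866025403784 -0.5
1.3623724357 0.786566092485 -7.75161061246e-18
-1.3623724357 -0.786566092485 -1.20955870128e-18
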