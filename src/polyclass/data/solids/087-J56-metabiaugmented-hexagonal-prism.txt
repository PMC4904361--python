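# J56 metabiaugmented hexagonal prism | Johnson | id 87
1 -0.112366584641 0.5
0.5 0.753658819144 0.5
-0.5 0.753658819144 0.5
-1 -0.112366584641 0.5
-0.5 -0.978391988425 0.5
0.5 -0.978391988425 0.5
1 -0.112366584641 -0.5
0.5 0.753658819144 -0.5
-0.5 0.753658819144 -0.5
-1 -0.112366584641 -0.5
-0.5 -0.978391988425 -0.5
0.5 -0.978391988425 -0.5
1.3623724357 0.674199507845 -7.28432119023e-18
-1.3623724357 0.674199507845 -7.28432119023e-18
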