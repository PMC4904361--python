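# disdyakis dodecahedron | Catalan | id 24
-0.320377241017 8.5401771125e-18 -0.320377241017
-0.320377241017 8.5401771125e-18 0.320377241017
-0.276142374915 -0.276142374915 0.276142374915
0.320377241017 8.5401771125e-18 0.320377241017
0.276142374915 0.276142374915 0.276142374915
2.13504427813e-18 0.320377241017 -0.320377241017
-0.320377241017 -0.320377241017 1.46154370605e-19
2.13504427813e-18 8.5401771125e-18 0.522407749927
2.13504427813e-18 -0.320377241017 0.320377241017
0.320377241017 8.5401771125e-18 -0.320377241017
0.276142374915 0.276142374915 -0.276142374915
0.320377241017 0.320377241017 1.46154370605e-19
-0.276142374915 -0.276142374915 -0.276142374915
2.13504427813e-18 8.5401771125e-18 -0.522407749927
0.276142374915 -0.276142374915 0.276142374915
2.13504427813e-18 -0.522407749927 5.81450655918e-17
2.13504427813e-18 -0.320377241017 -0.320377241017
0.522407749927 8.5401771125e-18 1.46154370605e-19
0.276142374915 -0.276142374915 -0.276142374915
0.320377241017 -0.320377241017 1.46154370605e-19
-0.522407749927 8.5401771125e-18 1.46154370605e-19
-0.276142374915 0.276142374915 0.276142374915
2.13504427813e-18 0.320377241017 0.320377241017
-0.276142374915 0.276142374915 -0.276142374915
2.13504427813e-18 0.522407749927 5.81450655918e-17
-0.320377241017 0.320377241017 -6.14161925508e-18
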