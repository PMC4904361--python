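# J76 diminished rhombicosidodecahedron | Johnson | id 107
0.598673654239 0.5 -1.9583766624
0.598673654239 -0.5 -1.9583766624
-0.401326345761 0.5 2.2776913151
-0.401326345761 0.5 -1.9583766624
-0.401326345761 -0.5 2.2776913151
-0.401326345761 -0.5 -1.9583766624
0.598673654239 2.11803398875 0.659657326352
0.598673654239 2.11803398875 -0.340342673648
0.598673654239 -2.11803398875 0.659657326352
0.598673654239 -2.11803398875 -0.340342673648
-0.401326345761 2.11803398875 0.659657326352
-0.401326345761 2.11803398875 -0.340342673648
-0.401326345761 -2.11803398875 0.659657326352
-0.401326345761 -2.11803398875 -0.340342673648
2.21670764299 0.5 0.659657326352
2.21670764299 0.5 -0.340342673648
2.21670764299 -0.5 0.659657326352
2.21670764299 -0.5 -0.340342673648
-2.01936033451 0.5 0.659657326352
-2.01936033451 0.5 -0.340342673648
-2.01936033451 -0.5 0.659657326352
-2.01936033451 -0.5 -0.340342673648
1.40769064861 0.809016994375 -1.4583766624
1.40769064861 -0.809016994375 -1.4583766624
-1.21034334014 0.809016994375 1.7776913151
-1.21034334014 0.809016994375 -1.4583766624
-1.21034334014 -0.809016994375 1.7776913151
-1.21034334014 -0.809016994375 -1.4583766624
0.907690648614 1.61803398875 1.46867432073
0.907690648614 1.61803398875 -1.14935966802
0.907690648614 -1.61803398875 1.46867432073
0.907690648614 -1.61803398875 -1.14935966802
-0.710343340136 1.61803398875 1.46867432073
-0.710343340136 1.61803398875 -1.14935966802
-0.710343340136 -1.61803398875 1.46867432073
-0.710343340136 -1.61803398875 -1.14935966802
1.71670764299 1.30901699437 0.968674320727
1.71670764299 1.30901699437 -0.649359668023
1.71670764299 -1.30901699437 0.968674320727
1.71670764299 -1.30901699437 -0.649359668023
-1.51936033451 1.30901699437 0.968674320727
-1.51936033451 1.30901699437 -0.649359668023
-1.51936033451 -1.30901699437 0.968674320727
-1.51936033451 -1.30901699437 -0.649359668023
1.90769064861 0 -1.14935966802
-1.71034334014 0 1.46867432073
-1.71034334014 0 -1.14935966802
0.0986736542386 1.30901699437 1.96867432073
0.0986736542386 1.30901699437 -1.64935966802
0.0986736542386 -1.30901699437 1.96867432073
0.0986736542386 -1.30901699437 -1.64935966802
1.40769064861 1.80901699437 0.159657326352
1.40769064861 -1.80901699437 0.159657326352
-1.21034334014 1.80901699437 0.159657326352
-1.21034334014 -1.80901699437 0.159657326352
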