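# deltoidal icositetrahedron | Catalan | id 23
0.453081839322 -0.453081839322 0.453081839322
0.453081839322 -0.453081839322 -0.453081839322
-0.453081839322 -0.453081839322 -0.453081839322
0.453081839322 0.453081839322 0.453081839322
-0.453081839322 -0.453081839322 0.453081839322
0.453081839322 0.453081839322 -0.453081839322
-0.453081839322 0.453081839322 0.453081839322
-0.453081839322 0.453081839322 -0.453081839322
0.585786437627 -0.585786437627 -2.38648193721e-17
0.828427124746 4.27008855625e-18 -1.23680835206e-17
0.585786437627 4.27008855625e-18 0.585786437627
0.585786437627 4.27008855625e-18 -0.585786437627
1.28102656688e-17 4.27008855625e-18 -0.828427124746
-0.585786437627 4.27008855625e-18 -0.585786437627
1.28102656688e-17 -0.585786437627 -0.585786437627
1.28102656688e-17 -0.828427124746 -1.23680835206e-17
1.28102656688e-17 -0.585786437627 0.585786437627
1.28102656688e-17 4.27008855625e-18 0.828427124746
-0.585786437627 -0.585786437627 -2.38648193721e-17
-0.828427124746 4.27008855625e-18 -1.23680835206e-17
-0.585786437627 4.27008855625e-18 0.585786437627
0.585786437627 0.585786437627 -2.38648193721e-17
1.28102656688e-17 0.585786437627 0.585786437627
1.28102656688e-17 0.585786437627 -0.585786437627
1.28102656688e-17 0.828427124746 -1.23680835206e-17
-0.585786437627 0.585786437627 -2.38648193721e-17
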