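# J49 augmented triangular prism | Johnson | id 80
0.506222989491 -0.123196062242 0.5
-0.359802414293 0.376803937758 0.5
-0.359802414293 -0.623196062242 0.5
0.506222989491 -0.123196062242 -0.5
-0.359802414293 0.376803937758 -0.5
-0.359802414293 -0.623196062242 -0.5
0.426763678192 0.739176373454 -6.55588907121e-17
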