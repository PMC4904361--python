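# deltoidal hexecontahedron | Catalan | id 29
-0.433084729318 -2.68602344667e-18 0.165423646591
0.165423646591 -0.433084729318 4.47670574446e-18
0.433084729318 -2.68602344667e-18 0.165423646591
0.267661082727 -0.267661082727 -0.267661082727
1.02964232122e-17 0.165423646591 0.433084729318
0.433084729318 2.30490902874e-17 -0.165423646591
0.267661082727 0.267661082727 0.267661082727
-0.267661082727 -0.267661082727 0.267661082727
1.02964232122e-17 -0.165423646591 0.433084729318
0.267661082727 -0.267661082727 0.267661082727
-0.433084729318 -2.84211371807e-17 -0.165423646591
-0.267661082727 -0.267661082727 -0.267661082727
-0.267661082727 0.267661082727 0.267661082727
0.267661082727 0.267661082727 -0.267661082727
0.165423646591 0.433084729318 1.33516117852e-17
1.02964232122e-17 0.165423646591 -0.433084729318
1.02964232122e-17 -0.165423646591 -0.433084729318
-0.165423646591 0.433084729318 1.33516117852e-17
-0.165423646591 -0.433084729318 4.47670574446e-18
-0.267661082727 0.267661082727 -0.267661082727
0.38196601125 -0.14589803375 -0.2360679775
0.2546440075 -2.68602344667e-18 0.412022659167
0.38196601125 0.14589803375 0.2360679775
-0.38196601125 -0.14589803375 0.2360679775
0.2360679775 -0.38196601125 -0.14589803375
-0.14589803375 0.2360679775 0.38196601125
0.412022659167 0.2546440075 4.47670574446e-18
0.38196601125 0.14589803375 -0.2360679775
0.472135955 -2.68602344667e-18 4.47670574446e-18
0.412022659167 -0.2546440075 -2.97867805704e-17
0.38196601125 -0.14589803375 0.2360679775
-0.38196601125 0.14589803375 -0.2360679775
-0.2546440075 -2.68602344667e-18 -0.412022659167
0.2360679775 0.38196601125 0.14589803375
0.14589803375 0.2360679775 0.38196601125
1.02964232122e-17 0.412022659167 0.2546440075
-0.2546440075 -2.68602344667e-18 0.412022659167
1.02964232122e-17 -2.68602344667e-18 0.472135955
-0.14589803375 -0.2360679775 0.38196601125
0.14589803375 -0.2360679775 0.38196601125
0.2360679775 -0.38196601125 0.14589803375
-0.472135955 -2.68602344667e-18 4.47670574446e-18
-0.38196601125 -0.14589803375 -0.2360679775
-0.38196601125 0.14589803375 0.2360679775
0.2546440075 -2.68602344667e-18 -0.412022659167
1.02964232122e-17 -2.68602344667e-18 -0.472135955
-0.412022659167 0.2546440075 5.80474574216e-18
-0.2360679775 0.38196601125 0.14589803375
0.2360679775 0.38196601125 -0.14589803375
0.14589803375 0.2360679775 -0.38196601125
1.02964232122e-17 -0.412022659167 -0.2546440075
-0.14589803375 -0.2360679775 -0.38196601125
0.14589803375 -0.2360679775 -0.38196601125
1.02964232122e-17 -0.412022659167 0.2546440075
1.02964232122e-17 -0.472135955 4.47670574446e-18
1.02964232122e-17 0.472135955 4.47670574446e-18
-0.412022659167 -0.2546440075 4.47670574446e-18
-0.2360679775 -0.38196601125 -0.14589803375
-0.2360679775 -0.38196601125 0.14589803375
1.02964232122e-17 0.412022659167 -0.2546440075
-0.14589803375 0.2360679775 -0.38196601125
-0.2360679775 0.38196601125 -0.14589803375
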