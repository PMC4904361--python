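# rhombic triacontahedron | Catalan | id 26
-3.46944695195e-18 -0.2360679775 -0.61803398875
-3.46944695195e-18 -0.2360679775 0.61803398875
-0.38196601125 -0.38196601125 -0.38196601125
-3.46944695195e-18 0.2360679775 -0.61803398875
-3.46944695195e-18 0.2360679775 0.61803398875
-0.2360679775 -0.61803398875 3.8633068003e-17
-0.38196601125 -0.38196601125 0.38196601125
0.38196601125 -0.38196601125 -0.38196601125
0.2360679775 0.61803398875 3.8633068003e-17
-0.61803398875 -1.39575779684e-17 -0.2360679775
0.38196601125 0.38196601125 -0.38196601125
0.61803398875 -1.39575779684e-17 -0.2360679775
0.2360679775 -0.61803398875 -1.00909793797e-17
0.38196601125 -0.38196601125 0.38196601125
0.61803398875 -1.39575779684e-17 0.2360679775
0.38196601125 0.38196601125 0.38196601125
-0.38196601125 0.38196601125 -0.38196601125
-0.2360679775 0.61803398875 -1.00909793797e-17
-0.61803398875 -1.39575779684e-17 0.2360679775
-0.38196601125 0.38196601125 0.38196601125
-3.46944695195e-18 -0.61803398875 -0.38196601125
-0.61803398875 -0.38196601125 1.60610092101e-18
-0.38196601125 1.73472347598e-18 -0.61803398875
0.38196601125 -7.89277008201e-17 -0.61803398875
-3.46944695195e-18 -0.61803398875 0.38196601125
0.61803398875 -0.38196601125 5.30013303932e-17
0.38196601125 1.73472347598e-18 0.61803398875
0.61803398875 0.38196601125 -4.97891285512e-17
-3.46944695195e-18 0.61803398875 -0.38196601125
-3.46944695195e-18 0.61803398875 0.38196601125
-0.38196601125 -7.89277008201e-17 0.61803398875
-0.61803398875 0.38196601125 -4.97891285512e-17
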