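# pentakis dodecahedron | Catalan | id 28
0.412022659167 -0.157378651667 -3.46944695195e-18
-8.67361737988e-18 -0.225884003553 -0.365487995263
0.2546440075 -0.2546440075 -0.2546440075
0.225884003553 -0.365487995263 2.98298658746e-17
0.2546440075 -0.2546440075 0.2546440075
-8.67361737988e-18 -0.225884003553 0.365487995263
0.365487995263 -6.93889390391e-18 0.225884003553
0.157378651667 -6.93889390391e-18 0.412022659167
-8.67361737988e-18 0.225884003553 0.365487995263
0.2546440075 0.2546440075 0.2546440075
-8.67361737988e-18 0.412022659167 0.157378651667
-0.412022659167 -0.157378651667 -3.46944695195e-18
-8.67361737988e-18 -0.412022659167 0.157378651667
-8.67361737988e-18 0.225884003553 -0.365487995263
-8.67361737988e-18 0.412022659167 -0.157378651667
0.157378651667 -4.92117531953e-19 -0.412022659167
0.365487995263 -6.93889390391e-18 -0.225884003553
0.412022659167 0.157378651667 -3.46944695195e-18
0.225884003553 0.365487995263 1.49915542095e-17
0.2546440075 0.2546440075 -0.2546440075
-0.412022659167 0.157378651667 -3.46944695195e-18
-0.225884003553 0.365487995263 -2.7614424578e-17
-0.2546440075 -0.2546440075 0.2546440075
-0.2546440075 -0.2546440075 -0.2546440075
-8.67361737988e-18 -0.412022659167 -0.157378651667
-0.225884003553 -0.365487995263 -3.67687597786e-17
-0.157378651667 -6.93889390391e-18 -0.412022659167
-0.2546440075 0.2546440075 -0.2546440075
-0.365487995263 -6.93889390391e-18 -0.225884003553
-0.2546440075 0.2546440075 0.2546440075
-0.365487995263 -6.93889390391e-18 0.225884003553
-0.157378651667 -6.93889390391e-18 0.412022659167
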