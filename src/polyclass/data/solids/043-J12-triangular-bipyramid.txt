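# J12 triangular bipyramid | Johnson | id 43
0.57735026919 -4.4408920985e-17 0
-0.288675134595 0.5 0
-0.288675134595 -0.5 0
3.33066907388e-17 -4.4408920985e-17 0.816496580928
3.33066907388e-17 -4.4408920985e-17 -0.816496580928
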