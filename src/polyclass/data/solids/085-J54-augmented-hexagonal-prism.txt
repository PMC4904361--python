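# J54 augmented hexagonal prism | Johnson | id 85
0.895202120331 -0.0605050840373 0.5
0.395202120331 0.805520319747 0.5
-0.604797879669 0.805520319747 0.5
-1.10479787967 -0.0605050840373 0.5
-0.604797879669 -0.926530487822 0.5
0.395202120331 -0.926530487822 0.5
0.895202120331 -0.0605050840373 -0.5
0.395202120331 0.805520319747 -0.5
-0.604797879669 0.805520319747 -0.5
-1.10479787967 -0.0605050840373 -0.5
-0.604797879669 -0.926530487822 -0.5
0.395202120331 -0.926530487822 -0.5
1.25757455603 0.726061008448 -7.84465358948e-18
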