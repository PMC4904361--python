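# J51 triaugmented triangular prism | Johnson | id 82
0.57735026919 -1.11022302463e-16 0.5
-0.288675134595 0.5 0.5
-0.288675134595 -0.5 0.5
0.57735026919 -1.11022302463e-16 -0.5
-0.288675134595 0.5 -0.5
-0.288675134595 -0.5 -0.5
0.497890957891 0.862372435696 -6.86165070142e-17
-0.995781915781 2.7476618027e-16 7.86886548328e-18
0.497890957891 -0.862372435696 1.35344486312e-17
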