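# J50 biaugmented triangular prism | Johnson | id 81
0.639586638926 -0.107796554462 0.5
-0.226438764858 0.392203445538 0.5
-0.226438764858 -0.607796554462 0.5
0.639586638926 -0.107796554462 -0.5
-0.226438764858 0.392203445538 -0.5
-0.226438764858 -0.607796554462 -0.5
0.560127327627 0.754575881234 -6.69247009353e-17
-0.933545546045 -0.107796554462 9.56067156218e-18
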