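# J92 triangular hebesphenorotunda | Johnson | id 123
0.5 0.288675134595 0.851986358941
-0.5 0.288675134595 0.851986358941
-7.52179954107e-17 -0.57735026919 0.851986358941
0.809016994375 1.04443644867 0.274636089751
1.30901699437 0.178411044887 0.274636089751
-1.30901699437 0.178411044887 0.274636089751
-0.809016994375 1.04443644867 0.274636089751
0.5 -1.22284749356 0.274636089751
-0.5 -1.22284749356 0.274636089751
1.23393595882e-16 1.51152262815 -0.0821860000216
-1.30901699437 -0.755761314076 -0.0821860000216
1.30901699437 -0.755761314076 -0.0821860000216
0.5 0.866025403784 -0.659536269211
1 -8.63506796931e-17 -0.659536269211
-1 4.80203210072e-16 -0.659536269211
-0.5 0.866025403784 -0.659536269211
0.5 -0.866025403784 -0.659536269211
-0.5 -0.866025403784 -0.659536269211
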