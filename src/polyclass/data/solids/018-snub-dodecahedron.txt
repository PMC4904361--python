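# snub dodecahedron | Archimedean | id 18
0.33092102473 0.374821658115 2.09705383525
0.847550046789 1.10315683507 1.64691794069
2.09705383525 0.33092102473 0.374821658115
0.192893711352 1.74618644099 1.24950378846
1.64691794069 0.847550046789 1.10315683507
0.567715369467 1.97783896542 -0.643029605914
0.374821658115 2.09705383525 0.33092102473
-0.728335176957 1.41526541626 1.45402422934
1.24950378846 0.192893711352 1.74618644099
1.10315683507 1.64691794069 0.847550046789
-1.74618644099 1.24950378846 -0.192893711352
-0.643029605914 0.567715369467 1.97783896542
-1.41526541626 1.45402422934 0.728335176957
1.45402422934 -0.728335176957 1.41526541626
1.74618644099 1.24950378846 0.192893711352
-0.567715369467 1.97783896542 0.643029605914
-1.64691794069 -0.847550046789 1.10315683507
-0.192893711352 -1.74618644099 1.24950378846
1.97783896542 -0.643029605914 0.567715369467
-1.24950378846 -0.192893711352 1.74618644099
0.728335176957 -1.41526541626 1.45402422934
1.41526541626 1.45402422934 -0.728335176957
-0.374821658115 2.09705383525 -0.33092102473
-1.45402422934 0.728335176957 1.41526541626
0.643029605914 -0.567715369467 1.97783896542
1.10315683507 -1.64691794069 -0.847550046789
1.24950378846 -0.192893711352 -1.74618644099
1.74618644099 -1.24950378846 -0.192893711352
1.45402422934 0.728335176957 -1.41526541626
-1.10315683507 1.64691794069 -0.847550046789
-1.97783896542 0.643029605914 0.567715369467
-0.33092102473 -0.374821658115 2.09705383525
1.41526541626 -1.45402422934 0.728335176957
1.97783896542 0.643029605914 -0.567715369467
-0.847550046789 1.10315683507 -1.64691794069
-0.33092102473 0.374821658115 -2.09705383525
-0.192893711352 1.74618644099 -1.24950378846
-2.09705383525 -0.33092102473 0.374821658115
-0.847550046789 -1.10315683507 1.64691794069
0.567715369467 -1.97783896542 0.643029605914
2.09705383525 -0.33092102473 -0.374821658115
0.728335176957 1.41526541626 -1.45402422934
-1.97783896542 -0.643029605914 -0.567715369467
-1.45402422934 -0.728335176957 -1.41526541626
-2.09705383525 0.33092102473 -0.374821658115
0.374821658115 -2.09705383525 -0.33092102473
1.64691794069 -0.847550046789 -1.10315683507
0.643029605914 0.567715369467 -1.97783896542
-1.64691794069 0.847550046789 -1.10315683507
-0.374821658115 -2.09705383525 0.33092102473
-0.567715369467 -1.97783896542 -0.643029605914
-1.41526541626 -1.45402422934 -0.728335176957
-1.10315683507 -1.64691794069 0.847550046789
-1.24950378846 0.192893711352 -1.74618644099
-1.74618644099 -1.24950378846 0.192893711352
0.33092102473 -0.374821658115 -2.09705383525
-0.643029605914 -0.567715369467 -1.97783896542
-0.728335176957 -1.41526541626 -1.45402422934
0.847550046789 -1.10315683507 -1.64691794069
0.192893711352 -1.74618644099 -1.24950378846
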