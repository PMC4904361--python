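# J65 augmented truncated tetrahedron | Johnson | id 96
0.188561808316 0.188561808316 1.22565175406
0.188561808316 -0.51854497287 -0.895668589503
-0.51854497287 0.188561808316 -0.895668589503
-0.51854497287 -0.51854497287 1.22565175406
0.188561808316 0.895668589503 0.51854497287
0.188561808316 -1.22565175406 -0.188561808316
-0.51854497287 0.895668589503 -0.188561808316
-0.51854497287 -1.22565175406 0.51854497287
0.895668589503 0.188561808316 0.51854497287
0.895668589503 -0.51854497287 -0.188561808316
-1.22565175406 0.188561808316 -0.188561808316
-1.22565175406 -0.51854497287 0.51854497287
0.424264068712 0.424264068712 -1.1313708499
0.424264068712 1.1313708499 -0.424264068712
1.1313708499 0.424264068712 -0.424264068712
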