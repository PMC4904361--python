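# truncated tetrahedron | Archimedean | id 6
0.353553390593 0.353553390593 1.06066017178
0.353553390593 -0.353553390593 -1.06066017178
-0.353553390593 0.353553390593 -1.06066017178
-0.353553390593 -0.353553390593 1.06066017178
0.353553390593 1.06066017178 0.353553390593
0.353553390593 -1.06066017178 -0.353553390593
-0.353553390593 1.06066017178 -0.353553390593
-0.353553390593 -1.06066017178 0.353553390593
1.06066017178 0.353553390593 0.353553390593
1.06066017178 -0.353553390593 -0.353553390593
-1.06066017178 0.353553390593 -0.353553390593
-1.06066017178 -0.353553390593 0.353553390593
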