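# tetrahedron | Platonic | id 1
0.353553390593 0.353553390593 0.353553390593
0.353553390593 -0.353553390593 -0.353553390593
-0.353553390593 0.353553390593 -0.353553390593
-0.353553390593 -0.353553390593 0.353553390593
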