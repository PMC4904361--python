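# triakis tetrahedron | Catalan | id 19
0.565685424949 -0.565685424949 -0.565685424949
-0.565685424949 0.565685424949 -0.565685424949
-0.565685424949 -0.565685424949 0.565685424949
0.565685424949 0.565685424949 0.565685424949
0.942809041582 0.942809041582 -0.942809041582
-0.942809041582 -0.942809041582 -0.942809041582
0.942809041582 -0.942809041582 0.942809041582
-0.942809041582 0.942809041582 0.942809041582
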