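# J52 augmented pentagonal prism | Johnson | id 83
0.748030846077 -0.074557766815 0.5
0.160245593785 0.73445922756 0.5
-0.79081092251 0.425442233185 0.5
-0.79081092251 -0.574557766815 0.5
0.160245593785 -0.88357476119 0.5
0.748030846077 -0.074557766815 -0.5
0.160245593785 0.73445922756 -0.5
-0.79081092251 0.425442233185 -0.5
-0.79081092251 -0.574557766815 -0.5
0.160245593785 -0.88357476119 -0.5
1.02619962275 0.74557766815 2.09744816352e-17
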