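# J87 augmented sphenocorona | Johnson | id 118
0.5 0.0723386907177 0.571693438563
-0.5 0.0723386907177 0.571693438563
0.5 0.925065633564 0.0493365098798
-0.5 0.925065633564 0.0493365098798
0.5 -0.780388252129 0.0493365098798
-0.5 -0.780388252129 0.0493365098798
0.789427626661 0.0723386907177 -0.385506461627
-0.789427626661 0.0723386907177 -0.385506461627
0 0.572338690718 -0.7416019857
0 -0.427661309282 -0.7416019857
0 -0.723386907177 0.913483978009
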