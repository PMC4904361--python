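# J86 sphenocorona | Johnson | id 117
0.5 0 0.663041836364
-0.5 0 0.663041836364
0.5 0.852726942846 0.140684907681
-0.5 0.852726942846 0.140684907681
0.5 -0.852726942846 0.140684907681
-0.5 -0.852726942846 0.140684907681
0.789427626661 0 -0.294158063827
-0.789427626661 0 -0.294158063827
0 0.5 -0.650253587899
0 -0.5 -0.650253587899
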