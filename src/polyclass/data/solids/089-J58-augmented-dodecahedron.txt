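# J58 augmented dodecahedron | Johnson | id 89
-0.767978737286 -0.809016994375 -0.742615699565
-0.767978737286 -0.809016994375 0.875418289184
-0.767978737286 0.809016994375 -0.742615699565
-0.767978737286 0.809016994375 0.875418289184
0.850055251464 -0.809016994375 -0.742615699565
0.850055251464 -0.809016994375 0.875418289184
0.850055251464 0.809016994375 -0.742615699565
0.850055251464 0.809016994375 0.875418289184
0.0410382570893 0.5 1.37541828918
0.0410382570893 0.5 -1.24261569957
0.0410382570893 -0.5 1.37541828918
0.0410382570893 -0.5 -1.24261569957
0.541038257089 1.30901699437 0.0664012948095
0.541038257089 -1.30901699437 0.0664012948095
-0.458961742911 1.30901699437 0.0664012948095
-0.458961742911 -1.30901699437 0.0664012948095
1.35005525146 0 0.56640129481
1.35005525146 0 -0.43359870519
-1.26797873729 0 0.56640129481
-1.26797873729 0 -0.43359870519
-0.820765141786 0 -1.32802589619
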