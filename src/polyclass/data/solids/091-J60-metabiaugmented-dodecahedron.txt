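# J60 metabiaugmented dodecahedron | Johnson | id 91
-0.769844112608 -0.745633940239 -0.784806822006
-0.769844112608 -0.745633940239 0.833227166744
-0.769844112608 0.872400048511 -0.784806822006
-0.769844112608 0.872400048511 0.833227166744
0.848189876142 -0.745633940239 -0.784806822006
0.848189876142 -0.745633940239 0.833227166744
0.848189876142 0.872400048511 -0.784806822006
0.848189876142 0.872400048511 0.833227166744
0.039172881767 0.563383054136 1.33322716674
0.039172881767 0.563383054136 -1.28480682201
0.039172881767 -0.436616945864 1.33322716674
0.039172881767 -0.436616945864 -1.28480682201
0.539172881767 1.37240004851 0.0242101723693
0.539172881767 -1.24563394024 0.0242101723693
-0.460827118233 1.37240004851 0.0242101723693
-0.460827118233 -1.24563394024 0.0242101723693
1.34818987614 0.0633830541364 0.524210172369
1.34818987614 0.0633830541364 -0.475789827631
-1.26984411261 0.0633830541364 0.524210172369
-1.26984411261 0.0633830541364 -0.475789827631
-0.822630517108 0.0633830541364 -1.37021701863
0.039172881767 -1.33104413686 0.886013571244
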