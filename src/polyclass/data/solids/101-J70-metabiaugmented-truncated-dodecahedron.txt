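# J70 metabiaugmented truncated dodecahedron | Johnson | id 101
-0.113243585473 0.683231970304 2.99703936796
-0.113243585473 0.683231970304 -2.85706259829
-0.113243585473 -0.316768029696 2.99703936796
-0.113243585473 -0.316768029696 -2.85706259829
0.386756414527 3.11028295343 0.0699883848303
0.386756414527 -2.74381901282 0.0699883848303
-0.613243585473 3.11028295343 0.0699883848303
-0.613243585473 -2.74381901282 0.0699883848303
2.81380739765 0.183231970304 0.56998838483
2.81380739765 0.183231970304 -0.43001161517
-3.0402945686 0.183231970304 0.56998838483
-3.0402945686 0.183231970304 -0.43001161517
0.386756414527 1.49224896468 2.68802237358
0.386756414527 1.49224896468 -2.54804560392
0.386756414527 -1.12578502407 2.68802237358
0.386756414527 -1.12578502407 -2.54804560392
-0.613243585473 1.49224896468 2.68802237358
-0.613243585473 1.49224896468 -2.54804560392
-0.613243585473 -1.12578502407 2.68802237358
-0.613243585473 -1.12578502407 -2.54804560392
1.1957734089 2.80126595905 0.56998838483
1.1957734089 2.80126595905 -0.43001161517
1.1957734089 -2.43480201845 0.56998838483
1.1957734089 -2.43480201845 -0.43001161517
-1.42226057985 2.80126595905 0.56998838483
-1.42226057985 2.80126595905 -0.43001161517
-1.42226057985 -2.43480201845 0.56998838483
-1.42226057985 -2.43480201845 -0.43001161517
2.50479040328 0.683231970304 1.37900537921
2.50479040328 0.683231970304 -1.23902860954
2.50479040328 -0.316768029696 1.37900537921
2.50479040328 -0.316768029696 -1.23902860954
-2.73127757422 0.683231970304 1.37900537921
-2.73127757422 0.683231970304 -1.23902860954
-2.73127757422 -0.316768029696 1.37900537921
-2.73127757422 -0.316768029696 -1.23902860954
1.1957734089 1.80126595905 2.18802237358
1.1957734089 1.80126595905 -2.04804560392
1.1957734089 -1.43480201845 2.18802237358
1.1957734089 -1.43480201845 -2.04804560392
-1.42226057985 1.80126595905 2.18802237358
-1.42226057985 1.80126595905 -2.04804560392
-1.42226057985 -1.43480201845 2.18802237358
-1.42226057985 -1.43480201845 -2.04804560392
1.50479040328 2.30126595905 1.37900537921
1.50479040328 2.30126595905 -1.23902860954
1.50479040328 -1.93480201845 1.37900537921
1.50479040328 -1.93480201845 -1.23902860954
-1.73127757422 2.30126595905 1.37900537921
-1.73127757422 2.30126595905 -1.23902860954
-1.73127757422 -1.93480201845 1.37900537921
-1.73127757422 -1.93480201845 -1.23902860954
2.00479040328 1.49224896468 1.68802237358
2.00479040328 1.49224896468 -1.54804560392
2.00479040328 -1.12578502407 1.68802237358
2.00479040328 -1.12578502407 -1.54804560392
-2.23127757422 1.49224896468 1.68802237358
-2.23127757422 1.49224896468 -1.54804560392
-2.23127757422 -1.12578502407 1.68802237358
-2.23127757422 -1.12578502407 -1.54804560392
2.05757680778 0.683231970304 -2.13345580054
2.05757680778 -0.316768029696 -2.13345580054
1.2485598134 -0.625785024071 -2.63345580054
0.748559813402 0.183231970304 -2.94247279492
1.2485598134 0.992248964679 -2.63345580054
-0.113243585473 -2.82922920945 0.931791783705
0.695773408902 -2.52021221507 1.43179178371
0.386756414527 -2.02021221507 2.24080877808
-0.613243585473 -2.02021221507 2.24080877808
-0.922260579848 -2.52021221507 1.43179178371
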