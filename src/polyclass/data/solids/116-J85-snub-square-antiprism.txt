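# J85 snub square antiprism | Johnson | id 116
0.707106781187 6.93889390391e-18 0.676868509031
9.18700601391e-17 0.707106781187 0.676868509031
-0.707106781187 9.35344995275e-17 0.676868509031
-8.1321151108e-17 -0.707106781187 0.676868509031
0.857865868455 0.857865868455 0.185607021282
-0.857865868455 0.857865868455 0.185607021282
-0.857865868455 -0.857865868455 0.185607021282
0.857865868455 -0.857865868455 0.185607021282
1.2285967175e-16 1.21320554587 -0.185607021282
-1.21320554587 1.55513722749e-16 -0.185607021282
-1.74289985941e-16 -1.21320554587 -0.185607021282
1.21320554587 -2.90210763787e-16 -0.185607021282
0.5 0.5 -0.676868509031
-0.5 0.5 -0.676868509031
-0.5 -0.5 -0.676868509031
0.5 -0.5 -0.676868509031
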