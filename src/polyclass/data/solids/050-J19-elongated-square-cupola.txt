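# J19 elongated square cupola | Johnson | id 50
0.707106781187 2.77555756156e-17 0.965685424949
9.8808954043e-17 0.707106781187 0.965685424949
-0.707106781187 1.14351181239e-16 0.965685424949
-7.43822572041e-17 -0.707106781187 0.965685424949
1.20710678119 0.5 0.258578643763
0.5 1.20710678119 0.258578643763
-0.5 1.20710678119 0.258578643763
-1.20710678119 0.5 0.258578643763
-1.20710678119 -0.5 0.258578643763
-0.5 -1.20710678119 0.258578643763
0.5 -1.20710678119 0.258578643763
1.20710678119 -0.5 0.258578643763
1.20710678119 0.5 -0.741421356237
0.5 1.20710678119 -0.741421356237
-0.5 1.20710678119 -0.741421356237
-1.20710678119 0.5 -0.741421356237
-1.20710678119 -0.5 -0.741421356237
-0.5 -1.20710678119 -0.741421356237
0.5 -1.20710678119 -0.741421356237
1.20710678119 -0.5 -0.741421356237
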