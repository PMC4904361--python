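# J17 gyroelongated square bipyramid | Johnson | id 48
0.707106781187 -1.11022302463e-17 0.420448207627
6.55022633043e-17 0.707106781187 0.420448207627
-0.707106781187 7.54933753773e-17 0.420448207627
-1.07688947943e-16 -0.707106781187 0.420448207627
0.5 0.5 -0.420448207627
-0.5 0.5 -0.420448207627
-0.5 -0.5 -0.420448207627
0.5 -0.5 -0.420448207627
2.22044604925e-17 -1.11022302463e-17 1.12755498881
2.22044604925e-17 -1.11022302463e-17 -1.12755498881
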