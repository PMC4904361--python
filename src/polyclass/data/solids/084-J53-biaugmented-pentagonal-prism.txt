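# J53 biaugmented pentagonal prism | Johnson | id 84
0.872857321385 -0.0683446195804 0.5
0.285072069093 0.740672374795 0.5
-0.665984447202 0.43165538042 0.5
-0.665984447202 -0.56834461958 0.5
0.285072069093 -0.877361613955 0.5
0.872857321385 -0.0683446195804 -0.5
0.285072069093 0.740672374795 -0.5
-0.665984447202 0.43165538042 -0.5
-0.665984447202 -0.56834461958 -0.5
0.285072069093 -0.877361613955 -0.5
1.15102609806 0.751790815385 2.11492689822e-17
-1.37309122839 -0.0683446195804 -1.92266081656e-18
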