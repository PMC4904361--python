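# J68 augmented truncated dodecahedron | Johnson | id 99
-0.12195463051 0.5 3.12437772037
-0.12195463051 0.5 -2.72972424587
-0.12195463051 -0.5 3.12437772037
-0.12195463051 -0.5 -2.72972424587
0.37804536949 2.92705098312 0.19732673725
0.37804536949 -2.92705098312 0.19732673725
-0.62195463051 2.92705098312 0.19732673725
-0.62195463051 -2.92705098312 0.19732673725
2.80509635262 1.7080354225e-18 0.69732673725
2.80509635262 1.7080354225e-18 -0.30267326275
-3.04900561363 1.7080354225e-18 0.69732673725
-3.04900561363 1.7080354225e-18 -0.30267326275
0.37804536949 1.30901699437 2.815360726
0.37804536949 1.30901699437 -2.4207072515
0.37804536949 -1.30901699437 2.815360726
0.37804536949 -1.30901699437 -2.4207072515
-0.62195463051 1.30901699437 2.815360726
-0.62195463051 1.30901699437 -2.4207072515
-0.62195463051 -1.30901699437 2.815360726
-0.62195463051 -1.30901699437 -2.4207072515
1.18706236387 2.61803398875 0.69732673725
1.18706236387 2.61803398875 -0.30267326275
1.18706236387 -2.61803398875 0.69732673725
1.18706236387 -2.61803398875 -0.30267326275
-1.43097162488 2.61803398875 0.69732673725
-1.43097162488 2.61803398875 -0.30267326275
-1.43097162488 -2.61803398875 0.69732673725
-1.43097162488 -2.61803398875 -0.30267326275
2.49607935824 0.5 1.50634373162
2.49607935824 0.5 -1.11169025712
2.49607935824 -0.5 1.50634373162
2.49607935824 -0.5 -1.11169025712
-2.73998861926 0.5 1.50634373162
-2.73998861926 0.5 -1.11169025712
-2.73998861926 -0.5 1.50634373162
-2.73998861926 -0.5 -1.11169025712
1.18706236387 1.61803398875 2.315360726
1.18706236387 1.61803398875 -1.9207072515
1.18706236387 -1.61803398875 2.315360726
1.18706236387 -1.61803398875 -1.9207072515
-1.43097162488 1.61803398875 2.315360726
-1.43097162488 1.61803398875 -1.9207072515
-1.43097162488 -1.61803398875 2.315360726
-1.43097162488 -1.61803398875 -1.9207072515
1.49607935824 2.11803398875 1.50634373162
1.49607935824 2.11803398875 -1.11169025712
1.49607935824 -2.11803398875 1.50634373162
1.49607935824 -2.11803398875 -1.11169025712
-1.73998861926 2.11803398875 1.50634373162
-1.73998861926 2.11803398875 -1.11169025712
-1.73998861926 -2.11803398875 1.50634373162
-1.73998861926 -2.11803398875 -1.11169025712
1.99607935824 1.30901699437 1.815360726
1.99607935824 1.30901699437 -1.4207072515
1.99607935824 -1.30901699437 1.815360726
1.99607935824 -1.30901699437 -1.4207072515
-2.23998861926 1.30901699437 1.815360726
-2.23998861926 1.30901699437 -1.4207072515
-2.23998861926 -1.30901699437 1.815360726
-2.23998861926 -1.30901699437 -1.4207072515
2.04886576274 0.5 -2.00611744812
2.04886576274 -0.5 -2.00611744812
1.23984876837 -0.809016994375 -2.50611744812
0.739848768365 -5.03793040595e-17 -2.8151344425
1.23984876837 0.809016994375 -2.50611744812
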