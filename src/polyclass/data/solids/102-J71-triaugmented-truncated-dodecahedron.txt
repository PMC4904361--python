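# J71 triaugmented truncated dodecahedron | Johnson | id 102
-0.105694013108 0.5 2.88667946252
-0.105694013108 0.5 -2.96742250372
-0.105694013108 -0.5 2.88667946252
-0.105694013108 -0.5 -2.96742250372
0.394305986892 2.92705098312 -0.0403715206
0.394305986892 -2.92705098312 -0.0403715206
-0.605694013108 2.92705098312 -0.0403715206
-0.605694013108 -2.92705098312 -0.0403715206
2.82135697002 1.18423789293e-17 0.4596284794
2.82135697002 1.18423789293e-17 -0.5403715206
-3.03274499623 1.18423789293e-17 0.4596284794
-3.03274499623 1.18423789293e-17 -0.5403715206
0.394305986892 1.30901699437 2.57766246815
0.394305986892 1.30901699437 -2.65840550935
0.394305986892 -1.30901699437 2.57766246815
0.394305986892 -1.30901699437 -2.65840550935
-0.605694013108 1.30901699437 2.57766246815
-0.605694013108 1.30901699437 -2.65840550935
-0.605694013108 -1.30901699437 2.57766246815
-0.605694013108 -1.30901699437 -2.65840550935
1.20332298127 2.61803398875 0.4596284794
1.20332298127 2.61803398875 -0.5403715206
1.20332298127 -2.61803398875 0.4596284794
1.20332298127 -2.61803398875 -0.5403715206
-1.41471100748 2.61803398875 0.4596284794
-1.41471100748 2.61803398875 -0.5403715206
-1.41471100748 -2.61803398875 0.4596284794
-1.41471100748 -2.61803398875 -0.5403715206
2.51233997564 0.5 1.26864547377
2.51233997564 0.5 -1.34938851497
2.51233997564 -0.5 1.26864547377
2.51233997564 -0.5 -1.34938851497
-2.72372800186 0.5 1.26864547377
-2.72372800186 0.5 -1.34938851497
-2.72372800186 -0.5 1.26864547377
-2.72372800186 -0.5 -1.34938851497
1.20332298127 1.61803398875 2.07766246815
1.20332298127 1.61803398875 -2.15840550935
1.20332298127 -1.61803398875 2.07766246815
1.20332298127 -1.61803398875 -2.15840550935
-1.41471100748 1.61803398875 2.07766246815
-1.41471100748 1.61803398875 -2.15840550935
-1.41471100748 -1.61803398875 2.07766246815
-1.41471100748 -1.61803398875 -2.15840550935
1.51233997564 2.11803398875 1.26864547377
1.51233997564 2.11803398875 -1.34938851497
1.51233997564 -2.11803398875 1.26864547377
1.51233997564 -2.11803398875 -1.34938851497
-1.72372800186 2.11803398875 1.26864547377
-1.72372800186 2.11803398875 -1.34938851497
-1.72372800186 -2.11803398875 1.26864547377
-1.72372800186 -2.11803398875 -1.34938851497
2.01233997564 1.30901699437 1.57766246815
2.01233997564 1.30901699437 -1.65840550935
2.01233997564 -1.30901699437 1.57766246815
2.01233997564 -1.30901699437 -1.65840550935
-2.22372800186 1.30901699437 1.57766246815
-2.22372800186 1.30901699437 -1.65840550935
-2.22372800186 -1.30901699437 1.57766246815
-2.22372800186 -1.30901699437 -1.65840550935
2.06512638014 0.5 -2.24381570597
2.06512638014 -0.5 -2.24381570597
1.25610938577 -0.809016994375 -2.74381570597
0.756109385767 -4.02449605527e-17 -3.05283270035
1.25610938577 0.809016994375 -2.74381570597
-0.105694013108 -3.01246117975 0.821431878275
0.703322981267 -2.70344418537 1.32143187827
0.394305986892 -2.20344418537 2.13044887265
-0.605694013108 -2.20344418537 2.13044887265
-0.914711007483 -2.70344418537 1.32143187827
-0.105694013108 3.01246117975 0.821431878275
-0.914711007483 2.70344418537 1.32143187827
-0.605694013108 2.20344418537 2.13044887265
0.394305986892 2.20344418537 2.13044887265
0.703322981267 2.70344418537 1.32143187827
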