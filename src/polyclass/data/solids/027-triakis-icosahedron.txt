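# triakis icosahedron | Catalan | id 27
2.60208521397e-18 0.122502196136 -0.320714913182
2.60208521397e-18 -0.122502196136 0.320714913182
2.60208521397e-18 -0.122502196136 -0.320714913182
0.320714913182 5.65532311763e-18 -0.122502196136
0.198212717045 0.198212717045 -0.198212717045
0.122502196136 0.320714913182 -3.51411221452e-18
-0.122502196136 -0.320714913182 -1.04083408559e-17
-0.198212717045 -0.198212717045 -0.198212717045
-0.320714913182 -1.34024598246e-17 -0.122502196136
0.198212717045 -0.198212717045 -0.198212717045
0.198212717045 -0.198212717045 0.198212717045
0.122502196136 -0.320714913182 -1.73025694972e-17
-0.122502196136 0.320714913182 -1.04083408559e-17
-0.198212717045 0.198212717045 0.198212717045
-0.320714913182 2.47131060599e-17 0.122502196136
2.60208521397e-18 0.122502196136 0.320714913182
0.198212717045 0.198212717045 0.198212717045
0.320714913182 2.47131060599e-17 0.122502196136
-0.198212717045 0.198212717045 -0.198212717045
-0.198212717045 -0.198212717045 0.198212717045
0.211145618 5.65532311763e-18 -0.3416407865
2.60208521397e-18 -0.3416407865 -0.211145618
2.60208521397e-18 -0.3416407865 0.211145618
0.3416407865 -0.211145618 -2.3131659086e-17
2.60208521397e-18 0.3416407865 -0.211145618
2.60208521397e-18 0.3416407865 0.211145618
0.3416407865 0.211145618 -2.64750608077e-17
0.211145618 5.65532311763e-18 0.3416407865
-0.3416407865 0.211145618 -1.93621919445e-17
-0.211145618 5.65532311763e-18 -0.3416407865
-0.3416407865 -0.211145618 2.3149773743e-18
-0.211145618 1.89740126628e-17 0.3416407865
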