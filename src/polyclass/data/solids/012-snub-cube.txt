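# snub cube | Archimedean | id 12
0.621226410557 0.337753973814 1.14261350893
0.621226410557 -0.337753973814 -1.14261350893
-0.621226410557 0.337753973814 -1.14261350893
-0.621226410557 -0.337753973814 1.14261350893
0.621226410557 1.14261350893 -0.337753973814
0.621226410557 -1.14261350893 0.337753973814
-0.621226410557 1.14261350893 0.337753973814
-0.621226410557 -1.14261350893 -0.337753973814
0.337753973814 0.621226410557 -1.14261350893
0.337753973814 -0.621226410557 1.14261350893
-0.337753973814 0.621226410557 1.14261350893
-0.337753973814 -0.621226410557 -1.14261350893
0.337753973814 1.14261350893 0.621226410557
0.337753973814 -1.14261350893 -0.621226410557
-0.337753973814 1.14261350893 -0.621226410557
-0.337753973814 -1.14261350893 0.621226410557
1.14261350893 0.621226410557 0.337753973814
1.14261350893 -0.621226410557 -0.337753973814
-1.14261350893 0.621226410557 -0.337753973814
-1.14261350893 -0.621226410557 0.337753973814
1.14261350893 0.337753973814 -0.621226410557
1.14261350893 -0.337753973814 0.621226410557
-1.14261350893 0.337753973814 0.621226410557
-1.14261350893 -0.337753973814 -0.621226410557
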