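# J26 gyrobifastigium | Johnson | id 57
0.5 0.5 0
0.5 -0.5 0
-0.5 0.5 0
-0.5 -0.5 0
0.5 0 0.866025403784
-0.5 0 0.866025403784
0 0.5 -0.866025403784
0 -0.5 -0.866025403784
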