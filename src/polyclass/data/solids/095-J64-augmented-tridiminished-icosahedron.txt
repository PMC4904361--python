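# J64 augmented tridiminished icosahedron | Johnson | id 95
-0.0968759866674 -0.537003334213 0.809016994375
-0.0968759866674 -0.537003334213 -0.809016994375
0.403124013333 0.772013660162 -2.2769346598e-18
-0.596875986667 0.772013660162 -2.2769346598e-18
-0.596875986667 -0.846020328588 -2.2769346598e-18
0.712141007708 -0.0370033342132 0.5
0.712141007708 -0.0370033342132 -0.5
-0.905892981042 -0.0370033342132 0.5
-0.905892981042 -0.0370033342132 -0.5
1.37188388001 0.524013013544 2.04924119382e-17
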