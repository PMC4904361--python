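# J88 sphenomegacorona | Johnson | id 119
0.639310531838 -0.700931384443 -0.407499706936
-0.103032760251 -1.01022044152 0.186862737928
0.757855932634 0.111527014198 0.163340321818
0.0155126405452 -0.197762042876 0.757702766682
0.0434796863633 0.00952968782554 -0.781973562328
-0.698863605726 -0.299759369248 -0.187611117464
1.03605080741 0.130263811937 -0.797001567333
0.449851737732 0.853578047498 -0.432053396574
0.0743246211297 0.764061048601 0.490424837101
-0.526361720741 0.67829615765 -0.3044464117
-0.819173849759 0.324852683451 0.584000979903
-0.868954021178 -0.663435213076 0.728254118904
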