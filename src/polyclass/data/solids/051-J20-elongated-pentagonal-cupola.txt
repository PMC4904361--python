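# J20 elongated pentagonal cupola | Johnson | id 51
0.850650808352 5.77315972805e-17 0.820584889695
0.26286555606 0.809016994375 0.820584889695
-0.688190960236 0.5 0.820584889695
-0.688190960236 -0.5 0.820584889695
0.26286555606 -0.809016994375 0.820584889695
1.53884176859 0.5 0.294853777576
0.951056516295 1.30901699437 0.294853777576
1.79012065035e-16 1.61803398875 0.294853777576
-0.951056516295 1.30901699437 0.294853777576
-1.53884176859 0.5 0.294853777576
-1.53884176859 -0.5 0.294853777576
-0.951056516295 -1.30901699437 0.294853777576
-2.17291964012e-16 -1.61803398875 0.294853777576
0.951056516295 -1.30901699437 0.294853777576
1.53884176859 -0.5 0.294853777576
1.53884176859 0.5 -0.705146222424
0.951056516295 1.30901699437 -0.705146222424
1.79012065035e-16 1.61803398875 -0.705146222424
-0.951056516295 1.30901699437 -0.705146222424
-1.53884176859 0.5 -0.705146222424
-1.53884176859 -0.5 -0.705146222424
-0.951056516295 -1.30901699437 -0.705146222424
-2.17291964012e-16 -1.61803398875 -0.705146222424
0.951056516295 -1.30901699437 -0.705146222424
1.53884176859 -0.5 -0.705146222424
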