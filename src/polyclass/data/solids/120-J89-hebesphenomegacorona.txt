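# J89 hebesphenomegacorona | Johnson | id 120
0.5 0.5 0.853947634843
-0.5 0.5 0.853947634843
0.5 -0.5 0.853947634843
-0.5 -0.5 0.853947634843
0.716844815713 0.5 -0.122258452978
-0.716844815713 0.5 -0.122258452978
0.716844815713 -0.5 -0.122258452978
-0.716844815713 -0.5 -0.122258452978
-0.5 0 -0.960696480443
0.5 0 -0.960696480443
0 1.10129604205 0.230695623359
0 -1.10129604205 0.230695623359
0 0.835659071722 -0.733377506646
0 -0.835659071722 -0.733377506646
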