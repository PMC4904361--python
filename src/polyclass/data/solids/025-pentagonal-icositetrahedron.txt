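# pentagonal icositetrahedron | Catalan | id 25
0.475829323253 -0.475829323253 -0.475829323253
0.475829323253 -0.658060423718 -0.140654073779
0.475829323253 0.658060423718 0.140654073779
0.475829323253 0.475829323253 0.475829323253
0.658060423718 0.475829323253 -0.140654073779
0.658060423718 -0.140654073779 -0.475829323253
0.475829323253 0.475829323253 -0.475829323253
0.475829323253 0.140654073779 -0.658060423718
0.658060423718 -0.475829323253 0.140654073779
0.658060423718 0.140654073779 0.475829323253
0.475829323253 -0.140654073779 0.658060423718
0.475829323253 -0.475829323253 0.475829323253
-0.475829323253 -0.475829323253 0.475829323253
-0.475829323253 -0.658060423718 0.140654073779
-0.140654073779 -0.475829323253 0.658060423718
0.140654073779 -0.658060423718 0.475829323253
-0.475829323253 0.475829323253 -0.475829323253
0.140654073779 0.658060423718 -0.475829323253
-0.140654073779 0.475829323253 -0.658060423718
-0.658060423718 -0.140654073779 0.475829323253
-0.140654073779 -0.658060423718 -0.475829323253
0.140654073779 -0.475829323253 -0.658060423718
-0.475829323253 0.658060423718 -0.140654073779
-0.658060423718 0.475829323253 0.140654073779
-0.658060423718 -0.475829323253 -0.140654073779
-0.658060423718 0.140654073779 -0.475829323253
-0.475829323253 -0.140654073779 -0.658060423718
-0.475829323253 -0.475829323253 -0.475829323253
-0.475829323253 0.140654073779 0.658060423718
0.140654073779 0.475829323253 0.658060423718
-0.475829323253 0.475829323253 0.475829323253
-0.140654073779 0.658060423718 0.475829323253
0.875186572002 -0 1.16865581539e-17
-2.92163953849e-18 -0.875186572002 1.16865581539e-17
-2.92163953849e-18 -0 -0.875186572002
-2.92163953849e-18 0.875186572002 1.16865581539e-17
-0.875186572002 0 1.16865581539e-17
-2.92163953849e-18 0 0.875186572002
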