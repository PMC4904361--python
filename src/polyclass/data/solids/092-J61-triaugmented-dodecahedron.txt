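# J61 triaugmented dodecahedron | Johnson | id 92
-0.832174550554 -0.785859438196 -0.785859438196
-0.832174550554 -0.785859438196 0.832174550554
-0.832174550554 0.832174550554 -0.785859438196
-0.832174550554 0.832174550554 0.832174550554
0.785859438196 -0.785859438196 -0.785859438196
0.785859438196 -0.785859438196 0.832174550554
0.785859438196 0.832174550554 -0.785859438196
0.785859438196 0.832174550554 0.832174550554
-0.0231575561793 0.523157556179 1.33217455055
-0.0231575561793 0.523157556179 -1.2858594382
-0.0231575561793 -0.476842443821 1.33217455055
-0.0231575561793 -0.476842443821 -1.2858594382
0.476842443821 1.33217455055 0.0231575561793
0.476842443821 -1.2858594382 0.0231575561793
-0.523157556179 1.33217455055 0.0231575561793
-0.523157556179 -1.2858594382 0.0231575561793
1.2858594382 0.0231575561793 0.523157556179
1.2858594382 0.0231575561793 -0.476842443821
-1.33217455055 0.0231575561793 0.523157556179
-1.33217455055 0.0231575561793 -0.476842443821
-0.884960955054 0.0231575561793 -1.37126963482
-0.0231575561793 -1.37126963482 0.884960955054
1.37126963482 0.884960955054 0.0231575561793
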