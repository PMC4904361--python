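# disdyakis triacontahedron | Catalan | id 30
0.267661082727 -1.79068229778e-18 -1.11917643611e-18
-0.157378651667 -0.157378651667 0.157378651667
0.216542364659 0.0827118232955 0.133830541364
-1.34301172334e-18 -1.79068229778e-18 -0.267661082727
0.216542364659 -0.0827118232955 -0.133830541364
-0.133830541364 -0.216542364659 -0.0827118232955
-0.133830541364 -0.216542364659 0.0827118232955
-0.0972653558335 -0.2546440075 -2.57522145832e-18
-1.34301172334e-18 -0.267661082727 -1.11917643611e-18
0.2546440075 -1.79068229778e-18 0.0972653558335
0.216542364659 -0.0827118232955 0.133830541364
0.133830541364 0.216542364659 0.0827118232955
0.157378651667 -0.157378651667 0.157378651667
0.133830541364 -0.216542364659 0.0827118232955
0.0972653558335 -0.2546440075 -2.57522145832e-18
-1.34301172334e-18 -1.79068229778e-18 0.267661082727
-0.0827118232955 -0.133830541364 -0.216542364659
-0.0827118232955 0.133830541364 -0.216542364659
-0.216542364659 0.0827118232955 -0.133830541364
-1.34301172334e-18 -0.0972653558335 -0.2546440075
-1.34301172334e-18 -0.2472135955 -0.1527864045
0.0827118232955 -0.133830541364 -0.216542364659
0.1527864045 7.84681199421e-18 0.2472135955
0.157378651667 0.157378651667 0.157378651667
0.0827118232955 0.133830541364 0.216542364659
0.133830541364 0.216542364659 -0.0827118232955
-0.157378651667 0.157378651667 -0.157378651667
-0.133830541364 0.216542364659 -0.0827118232955
-0.157378651667 -0.157378651667 -0.157378651667
-0.1527864045 -1.79068229778e-18 -0.2472135955
-0.216542364659 -0.0827118232955 -0.133830541364
-0.2472135955 -0.1527864045 -1.48046386955e-18
-0.216542364659 -0.0827118232955 0.133830541364
0.157378651667 -0.157378651667 -0.157378651667
0.2472135955 -0.1527864045 2.17477647791e-17
0.133830541364 -0.216542364659 -0.0827118232955
0.2546440075 -1.79068229778e-18 -0.0972653558335
0.2472135955 0.1527864045 3.14238836906e-18
0.1527864045 -1.79068229778e-18 -0.2472135955
0.157378651667 0.157378651667 -0.157378651667
0.216542364659 0.0827118232955 -0.133830541364
-1.34301172334e-18 0.0972653558335 -0.2546440075
0.0827118232955 0.133830541364 -0.216542364659
-0.2546440075 -1.79068229778e-18 0.0972653558335
-0.157378651667 0.157378651667 0.157378651667
-0.216542364659 0.0827118232955 0.133830541364
-1.34301172334e-18 0.0972653558335 0.2546440075
-0.0827118232955 0.133830541364 0.216542364659
0.0972653558335 0.2546440075 -2.57522145832e-18
-1.34301172334e-18 0.2472135955 -0.1527864045
-1.34301172334e-18 0.267661082727 -1.11917643611e-18
-0.2472135955 0.1527864045 -7.57889002682e-19
-0.2546440075 -1.79068229778e-18 -0.0972653558335
-0.267661082727 -1.79068229778e-18 -1.11917643611e-18
-0.1527864045 7.84681199421e-18 0.2472135955
-0.0827118232955 -0.133830541364 0.216542364659
-1.34301172334e-18 -0.0972653558335 0.2546440075
-1.34301172334e-18 -0.2472135955 0.1527864045
0.0827118232955 -0.133830541364 0.216542364659
-1.34301172334e-18 0.2472135955 0.1527864045
-0.0972653558335 0.2546440075 -2.57522145832e-18
-0.133830541364 0.216542364659 0.0827118232955
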