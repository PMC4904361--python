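# J90 disphenocingulum | Johnson | id 121
0.5 0 1.10443794208
-0.5 0 1.10443794208
0.5 0.767131113983 0.462947603915
-0.5 0.767131113983 0.462947603915
0.5 -0.767131113983 0.462947603915
-0.5 -0.767131113983 0.462947603915
0 0.5 -1.10443794208
0 -0.5 -1.10443794208
0.767131113983 0.5 -0.462947603915
0.767131113983 -0.5 -0.462947603915
-0.767131113983 0.5 -0.462947603915
-0.767131113983 -0.5 -0.462947603915
1.12648314708 -1.15949050368e-17 0.32500297595
-1.12648314708 1.15949050368e-17 0.32500297595
-1.15949050368e-17 -1.12648314708 -0.32500297595
1.15949050368e-17 1.12648314708 -0.32500297595
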