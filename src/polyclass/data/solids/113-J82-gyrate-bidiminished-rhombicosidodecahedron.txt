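# J82 gyrate bidiminished rhombicosidodecahedron | Johnson | id 113
0.29472135955 0.108541019662 2.02782112639
0.79472135955 -0.700475974712 1.71880413201
-0.567082039325 0.608541019662 1.94241092976
-0.567082039325 0.608541019662 -2.29365704774
-0.567082039325 -0.391458980338 1.94241092976
-0.567082039325 -0.391458980338 -2.29365704774
0.432917960675 2.22657500841 0.324376941013
0.432917960675 2.22657500841 -0.675623058987
0.432917960675 -2.00949296909 0.324376941013
0.432917960675 -2.00949296909 -0.675623058987
-0.567082039325 2.22657500841 0.324376941013
-0.567082039325 2.22657500841 -0.675623058987
-0.567082039325 -2.00949296909 0.324376941013
-0.567082039325 -2.00949296909 -0.675623058987
2.05095194942 0.608541019662 0.324376941013
2.05095194942 0.608541019662 -0.675623058987
2.05095194942 -0.391458980338 0.324376941013
2.05095194942 -0.391458980338 -0.675623058987
-2.18511602807 -0.391458980338 0.324376941013
-2.18511602807 -0.391458980338 -0.675623058987
0.79472135955 0.917558014037 1.71880413201
1.60373835392 -0.391458980338 1.21880413201
-1.3760990337 0.917558014037 1.44241092976
-1.3760990337 0.917558014037 -1.79365704774
-1.3760990337 -0.700475974712 1.44241092976
-1.3760990337 -0.700475974712 -1.79365704774
0.74193495505 1.72657500841 1.13339393539
0.74193495505 1.72657500841 -1.48464005336
0.74193495505 -1.50949296909 1.13339393539
0.74193495505 -1.50949296909 -1.48464005336
-0.8760990337 1.72657500841 1.13339393539
-0.8760990337 1.72657500841 -1.48464005336
-0.8760990337 -1.50949296909 1.13339393539
-0.8760990337 -1.50949296909 -1.48464005336
1.55095194942 1.41755801404 0.633393935387
1.55095194942 1.41755801404 -0.984640053362
1.55095194942 -1.20047597471 0.633393935387
1.55095194942 -1.20047597471 -0.984640053362
-1.68511602807 -1.20047597471 0.633393935387
-1.68511602807 -1.20047597471 -0.984640053362
1.60373835392 0.608541019662 1.21880413201
-1.8760990337 0.108541019662 1.13339393539
-1.8760990337 0.108541019662 -1.48464005336
-0.067082039325 1.41755801404 1.63339393539
-0.067082039325 1.41755801404 -1.98464005336
-0.067082039325 -1.20047597471 1.63339393539
-0.067082039325 -1.20047597471 -1.98464005336
1.24193495505 1.91755801404 -0.175623058987
1.24193495505 -1.70047597471 -0.175623058987
-1.3760990337 -1.70047597471 -0.175623058987
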