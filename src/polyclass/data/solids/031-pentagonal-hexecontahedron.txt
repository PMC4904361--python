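# pentagonal hexecontahedron | Catalan | id 31
-0.476859479327 0.0496820178716 0.0438630583606
0.258563111466 -0.0852325570877 0.397074001182
0.476859479327 -0.0496820178716 0.0438630583606
0.0496820178716 0.0438630583606 -0.476859479327
-0.277961168639 -0.277961168639 -0.277961168639
-0.209482808994 -0.374500844228 -0.218296367862
0.424182862099 -0.187591192188 -0.129095615448
0.44975061841 -0.171789449771 3.8230698314e-17
-0.0438630583606 -0.476859479327 -0.0496820178716
-0.129095615448 -0.424182862099 0.187591192188
-3.016910393e-18 -0.44975061841 -0.171789449771
-0.0852325570877 -0.397074001182 -0.258563111466
-0.374500844228 0.218296367862 0.209482808994
-0.0496820178716 -0.0438630583606 -0.476859479327
-0.218296367862 -0.209482808994 -0.374500844228
-0.258563111466 -0.0852325570877 -0.397074001182
-0.171789449771 -2.48942428652e-16 -0.44975061841
-0.171789449771 -1.97192608278e-17 0.44975061841
-0.258563111466 0.0852325570877 0.397074001182
0.28926828714 -0.165619750634 -0.34739198331
0.187591192188 -0.129095615448 -0.424182862099
0.258563111466 0.0852325570877 -0.397074001182
0.171789449771 -2.33367797031e-16 -0.44975061841
0.0852325570877 0.397074001182 -0.258563111466
0.218296367862 0.209482808994 -0.374500844228
0.34739198331 0.28926828714 0.165619750634
0.424182862099 0.187591192188 0.129095615448
0.44975061841 0.171789449771 -1.19742346726e-16
0.476859479327 0.0496820178716 -0.0438630583606
-0.187591192188 0.129095615448 -0.424182862099
-0.28926828714 0.165619750634 -0.34739198331
-0.165619750634 0.34739198331 -0.28926828714
-0.277961168639 0.277961168639 -0.277961168639
-3.016910393e-18 0.44975061841 -0.171789449771
-0.0438630583606 0.476859479327 0.0496820178716
0.0438630583606 0.476859479327 -0.0496820178716
-0.129095615448 0.424182862099 -0.187591192188
-0.424182862099 -0.187591192188 0.129095615448
-0.34739198331 -0.28926828714 0.165619750634
0.374500844228 -0.218296367862 0.209482808994
0.397074001182 -0.258563111466 0.0852325570877
-0.165619750634 -0.34739198331 0.28926828714
-0.277961168639 -0.277961168639 0.277961168639
-0.28926828714 -0.165619750634 0.34739198331
-0.187591192188 -0.129095615448 0.424182862099
0.277961168639 -0.277961168639 -0.277961168639
0.34739198331 -0.28926828714 -0.165619750634
0.129095615448 -0.424182862099 -0.187591192188
0.165619750634 -0.34739198331 -0.28926828714
-0.424182862099 0.187591192188 -0.129095615448
-0.34739198331 0.28926828714 -0.165619750634
-0.44975061841 0.171789449771 -2.61965476606e-16
-0.397074001182 0.258563111466 0.0852325570877
0.129095615448 0.424182862099 0.187591192188
-3.016910393e-18 0.44975061841 0.171789449771
0.171789449771 -2.64362014253e-16 0.44975061841
0.0496820178716 -0.0438630583606 0.476859479327
-0.0496820178716 0.0438630583606 0.476859479327
0.209482808994 0.374500844228 -0.218296367862
0.277961168639 0.277961168639 -0.277961168639
0.397074001182 0.258563111466 -0.0852325570877
0.374500844228 0.218296367862 -0.209482808994
-0.374500844228 -0.218296367862 -0.209482808994
-0.476859479327 -0.0496820178716 -0.0438630583606
-0.44975061841 -0.171789449771 -3.03695610905e-16
-0.397074001182 -0.258563111466 -0.0852325570877
-3.016910393e-18 -0.44975061841 0.171789449771
0.0438630583606 -0.476859479327 0.0496820178716
-0.277961168639 0.277961168639 0.277961168639
-0.209482808994 0.374500844228 0.218296367862
-0.218296367862 0.209482808994 0.374500844228
-0.0852325570877 0.397074001182 0.258563111466
0.28926828714 0.165619750634 0.34739198331
0.277961168639 0.277961168639 0.277961168639
0.165619750634 0.34739198331 0.28926828714
0.187591192188 0.129095615448 0.424182862099
0.277961168639 -0.277961168639 0.277961168639
0.218296367862 -0.209482808994 0.374500844228
0.209482808994 -0.374500844228 0.218296367862
0.0852325570877 -0.397074001182 0.258563111466
-0.42942296947 1.58552306247e-16 0.265397990682
-3.016910393e-18 -0.265397990682 -0.42942296947
0.42942296947 1.0250636315e-16 0.265397990682
0.42942296947 -6.85157150343e-17 -0.265397990682
-3.016910393e-18 0.265397990682 -0.42942296947
-0.265397990682 -0.42942296947 -1.59493040698e-17
-0.265397990682 0.42942296947 -6.11692950407e-17
0.265397990682 0.42942296947 -3.14481138412e-17
-0.42942296947 1.72973550704e-16 -0.265397990682
0.265397990682 -0.42942296947 1.39961415982e-16
-3.016910393e-18 0.265397990682 0.42942296947
-3.016910393e-18 -0.265397990682 0.42942296947
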