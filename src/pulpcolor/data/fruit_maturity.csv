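fruit,titratable_acidity,total_soluble_solids,maturity_index
Araza,2.40,3.83,1.60
Blackberry,2.81,12.69,4.51
Andean blueberry,0.96,11.81,12.39
Naranjilla,2.58,9.55,3.72
Tamarillo,2.09,12.43,5.94
Goldenberry,1.42,13.73,9.64
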