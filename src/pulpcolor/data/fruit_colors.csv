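fruit,L_mean,L_sd,a_mean,a_sd,b_mean,b_sd
Araza,49.63,2.94,-0.89,0.40,22.73,2.84
Blackberry,10.68,2.23,13.80,3.90,4.95,1.70
Andean blueberry,20.80,1.50,3.52,1.10,3.16,0.95
Naranjilla,40.10,1.92,-4.25,0.60,22.04,2.62
Tamarillo,51.75,2.93,9.06,0.71,32.68,2.83
Goldenberry,35.70,2.46,7.10,0.51,25.39,3.55
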