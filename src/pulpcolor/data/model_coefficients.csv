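fruit,analyte,b0,b1,b2,b3,r2
Blackberry,TAC,1644.47,-13.53,-12.56,18.42,0.82
Blackberry,TPC,8375.00,-41.15,-132.30,18.79,0.82
Andean blueberry,TAC,-3206.38,233.19,96.97,264.90,0.81
Andean blueberry,TPC,7095.72,33.44,143.50,-308.63,0.82
Naranjilla,TCC,129.24,-1.04,1.47,-0.98,0.84
Naranjilla,TPC,1151.18,-15.69,-74.94,-5.58,0.84
Tamarillo,TCC,79.29,-1.12,3.93,3.35,0.98
Tamarillo,TPC,1247.55,-5.53,53.00,-11.51,0.75
Goldenberry,TCC,-24.31,2.19,2.41,-0.23,0.85
Goldenberry,TPC,-142.76,9.85,10.09,-1.91,0.88
Araza,TCC,83.52,-0.84,-5.88,0.70,0.93
Araza,TPC,-4974.64,381.95,932.80,-450.89,0.88
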