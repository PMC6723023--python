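fruit,analyte,experimental_mean,cv_e,predicted_mean,cv_p
Blackberry,TAC,1416.69,11.20,1413.00,0.85
Andean blueberry,TAC,2682.30,2.66,2761.24,5.74
Naranjilla,TCC,57.93,6.05,58.42,2.36
Tamarillo,TCC,123.18,4.65,133.67,1.95
Goldenberry,TCC,65.21,10.84,64.93,3.10
Araza,TCC,62.85,1.92,61.96,1.09
Blackberry,TPC,6352.28,4.77,5995.62,3.38
Andean blueberry,TPC,7254.62,10.86,7315.73,2.22
Naranjilla,TPC,897.58,6.32,912.50,2.02
Tamarillo,TPC,1062.77,10.26,1055.45,0.72
Goldenberry,TPC,259.93,11.61,233.68,3.24
Araza,TPC,3507.79,13.97,3256.33,6.94
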