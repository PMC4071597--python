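element,isotope_mass,abundance,nominal_shift
Br,78.9183376,0.5069,0
Br,80.9162906,0.4931,2
C,12.0,0.9893,0
C,13.0033548351,0.0107,1
Cl,34.96885271,0.7576,0
Cl,36.96590259,0.2424,2
F,18.9984031627,1.0,0
H,1.0078250319,0.999885,0
H,2.0141017781,0.000115,1
I,126.9044719,1.0,0
K,38.9637064864,0.932581,0
K,39.963998166,0.000117,1
K,40.9618252579,0.067302,2
N,14.0030740052,0.99636,0
N,15.0001088989,0.00364,1
Na,22.989769282,1.0,0
O,15.9949146221,0.99757,0
O,16.9991315,0.00038,1
O,17.9991604,0.00205,2
P,30.973761512,1.0,0
S,31.9720706912,0.9499,0
S,32.9714585909,0.0075,1
S,33.96786699,0.0425,2
S,35.967080762,0.0001,4
Si,27.976926535,0.92223,0
Si,28.9764946653,0.04685,1
Si,29.973770137,0.03092,2
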