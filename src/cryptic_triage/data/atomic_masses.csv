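element,monoisotopic_da,average_da
H,1.00782503207,1.008
He,4.00260325413,4.0026
Li,7.0160034366,6.94
Be,9.012183065,9.0122
B,11.00930536,10.81
C,12.0,12.011
N,14.0030740048,14.007
O,15.9949146196,15.999
F,18.99840316273,18.998403163
Na,22.989769282,22.98976928
Mg,23.985041697,24.305
Al,26.98153853,26.9815385
Si,27.97692653465,28.085
P,30.97376199842,30.973761998
S,31.9720711744,32.06
Cl,34.968852682,35.45
K,38.9637064864,39.0983
Ca,39.962590863,40.078
Cr,51.94050623,51.9961
Mn,54.93804391,54.938044
Fe,55.93493633,55.845
Co,58.93319429,58.933194
Ni,57.93534241,58.6934
Cu,62.92959772,63.546
Zn,63.92914201,65.38
As,74.92159457,74.921595
Se,79.9165218,78.971
Br,78.9183376,79.904
Sn,119.90220163,118.71
I,126.9044719,126.90447
Pt,194.9647917,195.084
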