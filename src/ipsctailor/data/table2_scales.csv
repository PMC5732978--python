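cell,s_NaCa,c_NaCa,s_Ks,c_Ks,s_Kr,c_Kr,s_K1,c_K1,s_f,c_f
1,3.32,28.5,139,71.2,,,,,,
2,2.08,21.2,129,78.5,,,,,,
3,7.55,50.3,125,49.5,,,,,,
4,21.1,43,467,56.8,,,,,,
5,6.89,29.9,270,70,,,,,1.18,
6,9.3,42.4,211,57.4,,,,,,
7,0.951,29.6,37.6,69.9,,,,,,
8,1.54,56.7,19.5,42.8,,,0.118,0.000258,,
9,1.7,35.2,52,64.3,,,,,,
10,1.67,98.6,,,,,0.104,0.000362,,
11,0.38,16.7,31.5,82.5,,,,,,
12,0.696,38.2,18.6,60.9,,,,,,
13,3.05,25,153,74.7,,,,,,
14,1.28,14.7,125,84.9,,,,,,
15,1.19,34.1,38.3,65.3,,,,,,
16,3.02,51.4,47.3,48,,,,,,
17,2.35,59,27,40.4,,,,,,
18,4.03,32.7,138,66.9,,,,,,
19,5.74,73.4,28.9,22,1.84,4.5,0.513,0.000388,,
20,2.35,80.5,9.18,18.8,,,1.18,0.0024,,
21,3.77,40.2,93.7,59.6,,,,,,
22,13.9,44.6,288,55.1,,,,,,
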