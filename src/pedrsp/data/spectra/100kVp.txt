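# 100kVp: tungsten-anode model, 100 kVp, filters {'Al': 8.0}
10.0 1.13462656e-25
11.0 1.05673586e-19
12.0 1.50838370e-15
13.0 1.43630103e-12
14.0 2.22266797e-10
15.0 9.79330081e-09
16.0 1.72291910e-07
17.0 1.60467410e-06
18.0 9.33027597e-06
19.0 3.80377904e-05
20.0 1.18186678e-04
21.0 2.82595385e-04
22.0 5.81203199e-04
23.0 1.05961607e-03
24.0 1.75261855e-03
25.0 2.67771883e-03
26.0 3.83286797e-03
27.0 5.19798789e-03
28.0 6.73901317e-03
29.0 8.41298835e-03
30.0 1.01730616e-02
31.0 1.16527466e-02
32.0 1.31083906e-02
33.0 1.45161805e-02
34.0 1.58566529e-02
35.0 1.71146175e-02
36.0 1.82788642e-02
37.0 1.93417430e-02
38.0 2.02986851e-02
39.0 2.11477131e-02
40.0 2.18889700e-02
41.0 2.22451780e-02
42.0 2.25238687e-02
43.0 2.27293931e-02
44.0 2.28662378e-02
45.0 2.29389302e-02
46.0 2.29519639e-02
47.0 2.29097415e-02
48.0 2.28165323e-02
49.0 2.26764415e-02
50.0 2.24933886e-02
51.0 2.21346734e-02
52.0 2.17556338e-02
53.0 2.13584833e-02
54.0 2.09452637e-02
55.0 2.05178560e-02
56.0 2.00779907e-02
57.0 1.96272585e-02
58.0 2.77443246e-02
59.0 3.46393911e-02
60.0 1.82238665e-02
61.0 1.76687934e-02
62.0 1.71176092e-02
63.0 1.65705969e-02
64.0 1.60280034e-02
65.0 1.54900432e-02
66.0 1.49569011e-02
67.0 1.96193384e-02
68.0 1.39056813e-02
69.0 1.33878510e-02
70.0 1.28753382e-02
71.0 1.23682187e-02
72.0 1.18665526e-02
73.0 1.13703856e-02
74.0 1.08797509e-02
75.0 1.03946699e-02
76.0 9.91515371e-03
77.0 9.44120433e-03
78.0 8.97281531e-03
79.0 8.50997283e-03
80.0 8.05265642e-03
81.0 7.58649377e-03
82.0 7.12797987e-03
83.0 6.67693459e-03
84.0 6.23318294e-03
85.0 5.79655490e-03
86.0 5.36688530e-03
87.0 4.94401366e-03
88.0 4.52778406e-03
89.0 4.11804499e-03
90.0 3.71464925e-03
91.0 3.31745377e-03
92.0 2.92631953e-03
93.0 2.54111139e-03
94.0 2.16169801e-03
95.0 1.78795171e-03
96.0 1.41974836e-03
97.0 1.05696728e-03
98.0 6.99491089e-04
99.0 3.47205666e-04
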