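# 140kVp: tungsten-anode model, 140 kVp, filters {'Al': 8.0}
10.0 6.70356657e-26
11.0 6.26495983e-20
12.0 8.97410750e-16
13.0 8.57594685e-13
14.0 1.33198344e-10
15.0 5.89077346e-09
16.0 1.04030198e-07
17.0 9.72671074e-07
18.0 5.67796365e-06
19.0 2.32416937e-05
20.0 7.25123405e-05
21.0 1.74115356e-04
22.0 3.59639628e-04
23.0 6.58560704e-04
24.0 1.09416783e-03
25.0 1.67939822e-03
26.0 2.41517793e-03
27.0 3.29111446e-03
28.0 4.28779458e-03
29.0 5.37981149e-03
30.0 6.53880611e-03
31.0 7.52935630e-03
32.0 8.51562165e-03
33.0 9.48229527e-03
34.0 1.04165904e-02
35.0 1.13082469e-02
36.0 1.21493967e-02
37.0 1.29343445e-02
38.0 1.36593027e-02
39.0 1.43221128e-02
40.0 1.49219718e-02
41.0 1.52676153e-02
42.0 1.55665800e-02
43.0 1.58211066e-02
44.0 1.60335637e-02
45.0 1.62063874e-02
46.0 1.63420331e-02
47.0 1.64429376e-02
48.0 1.65114899e-02
49.0 1.65500100e-02
50.0 1.65607321e-02
51.0 1.64444436e-02
52.0 1.63141824e-02
53.0 1.61712632e-02
54.0 1.60169047e-02
55.0 1.58522360e-02
56.0 1.56783010e-02
57.0 1.54960646e-02
58.0 2.85158345e-02
59.0 3.96594858e-02
60.0 1.49081125e-02
61.0 1.46393407e-02
62.0 1.43716375e-02
63.0 1.41052015e-02
64.0 1.38402093e-02
65.0 1.35768177e-02
66.0 1.33151653e-02
67.0 2.10492183e-02
68.0 1.27975528e-02
69.0 1.25417941e-02
70.0 1.22881802e-02
71.0 1.20367818e-02
72.0 1.17876597e-02
73.0 1.15408653e-02
74.0 1.12964421e-02
75.0 1.10544258e-02
76.0 1.08148456e-02
77.0 1.05777245e-02
78.0 1.03430798e-02
79.0 1.01109242e-02
80.0 9.88126540e-03
81.0 9.63588606e-03
82.0 9.39450913e-03
83.0 9.15704178e-03
84.0 8.92339376e-03
85.0 8.69347729e-03
86.0 8.46720701e-03
87.0 8.24449994e-03
88.0 8.02527538e-03
89.0 7.80945485e-03
90.0 7.59696205e-03
91.0 7.38772278e-03
92.0 7.18166488e-03
93.0 6.97871817e-03
94.0 6.77881440e-03
95.0 6.58188719e-03
96.0 6.38787195e-03
97.0 6.19670587e-03
98.0 6.00832783e-03
99.0 5.82267836e-03
100.0 5.63969960e-03
101.0 5.45468554e-03
102.0 5.27263830e-03
103.0 5.09348456e-03
104.0 4.91715343e-03
105.0 4.74357639e-03
106.0 4.57268711e-03
107.0 4.40442144e-03
108.0 4.23871728e-03
109.0 4.07551453e-03
110.0 3.91475495e-03
111.0 3.75638215e-03
112.0 3.60034150e-03
113.0 3.44658002e-03
114.0 3.29504639e-03
115.0 3.14569083e-03
116.0 2.99846503e-03
117.0 2.85332217e-03
118.0 2.71021679e-03
119.0 2.56910477e-03
120.0 2.42994327e-03
121.0 2.29269070e-03
122.0 2.15730667e-03
123.0 2.02375192e-03
124.0 1.89198832e-03
125.0 1.76197880e-03
126.0 1.63368734e-03
127.0 1.50707889e-03
128.0 1.38211939e-03
129.0 1.25877569e-03
130.0 1.13701555e-03
131.0 1.01680758e-03
132.0 8.98121252e-04
133.0 7.80926830e-04
134.0 6.65195367e-04
135.0 5.50898673e-04
136.0 4.38009290e-04
137.0 3.26500466e-04
138.0 2.16346137e-04
139.0 1.07520901e-04
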