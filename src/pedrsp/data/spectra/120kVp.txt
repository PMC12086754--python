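# 120kVp: tungsten-anode model, 120 kVp, filters {'Al': 8.0}
10.0 8.37534377e-26
11.0 7.81632233e-20
12.0 1.11802737e-15
13.0 1.06686513e-12
14.0 1.65455621e-10
15.0 7.30632506e-09
16.0 1.28830431e-07
17.0 1.20266728e-06
18.0 7.00939172e-06
19.0 2.86451538e-05
20.0 8.92232543e-05
21.0 2.13881239e-04
22.0 4.41020717e-04
23.0 8.06174521e-04
24.0 1.33704052e-03
25.0 2.04845693e-03
26.0 2.94048871e-03
27.0 3.99940029e-03
28.0 5.20057254e-03
29.0 6.51227683e-03
30.0 7.89942839e-03
31.0 9.07755189e-03
32.0 1.02452523e-02
33.0 1.13840379e-02
34.0 1.24785912e-02
35.0 1.35167503e-02
36.0 1.44893213e-02
37.0 1.53897893e-02
38.0 1.62139785e-02
39.0 1.69596981e-02
40.0 1.76263985e-02
41.0 1.79891436e-02
42.0 1.82940187e-02
43.0 1.85439920e-02
44.0 1.87421670e-02
45.0 1.88917094e-02
46.0 1.89957889e-02
47.0 1.90575340e-02
48.0 1.90799976e-02
49.0 1.90661321e-02
50.0 1.90187708e-02
51.0 1.88245954e-02
52.0 1.86139669e-02
53.0 1.83885243e-02
54.0 1.81497840e-02
55.0 1.78991473e-02
56.0 1.76379078e-02
57.0 1.73672581e-02
58.0 2.82034367e-02
59.0 3.74591882e-02
60.0 1.65094006e-02
61.0 1.61433558e-02
62.0 1.57792743e-02
63.0 1.54173882e-02
64.0 1.50579023e-02
65.0 1.47009972e-02
66.0 1.43468311e-02
67.0 2.07220081e-02
68.0 1.36472504e-02
69.0 1.33020592e-02
70.0 1.29600572e-02
71.0 1.26213195e-02
72.0 1.22859090e-02
73.0 1.19538778e-02
74.0 1.16252676e-02
75.0 1.13001115e-02
76.0 1.09784343e-02
77.0 1.06602537e-02
78.0 1.03455804e-02
79.0 1.00344196e-02
80.0 9.72677092e-03
81.0 9.40484482e-03
82.0 9.08818331e-03
83.0 8.77666348e-03
84.0 8.47016584e-03
85.0 8.16857426e-03
86.0 7.87177583e-03
87.0 7.57966082e-03
88.0 7.29212259e-03
89.0 7.00905743e-03
90.0 6.73036457e-03
91.0 6.45594603e-03
92.0 6.18570653e-03
93.0 5.91955349e-03
94.0 5.65739683e-03
95.0 5.39914899e-03
96.0 5.14472481e-03
97.0 4.89404148e-03
98.0 4.64701842e-03
99.0 4.40357727e-03
100.0 4.16364178e-03
101.0 3.92379306e-03
102.0 3.68777377e-03
103.0 3.45548947e-03
104.0 3.22684886e-03
105.0 3.00176366e-03
106.0 2.78014845e-03
107.0 2.56192058e-03
108.0 2.34700006e-03
109.0 2.13530944e-03
110.0 1.92677370e-03
111.0 1.72132019e-03
112.0 1.51887850e-03
113.0 1.31938039e-03
114.0 1.12275971e-03
115.0 9.28952299e-04
116.0 7.37895940e-04
117.0 5.49530261e-04
118.0 3.63796678e-04
119.0 1.80638327e-04
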