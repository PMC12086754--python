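# 140kVp-Sn: tungsten-anode model, 140 kVp, filters {'Al': 8.0, 'Sn': 0.4}
10.0 2.13186692e-28
11.0 7.90785090e-22
12.0 3.03746952e-17
13.0 5.99866730e-14
14.0 1.61005483e-11
15.0 1.08446578e-09
16.0 2.66677828e-08
17.0 3.24309965e-07
18.0 2.33926669e-06
19.0 1.13767806e-05
20.0 4.09089535e-05
21.0 1.10177906e-04
22.0 2.50672287e-04
23.0 4.98271856e-04
24.0 8.88001735e-04
25.0 1.44774579e-03
26.0 2.19597860e-03
27.0 3.13416974e-03
28.0 4.25172341e-03
29.0 5.52711248e-03
30.0 1.42208313e-03
31.0 1.91746791e-03
32.0 2.49555340e-03
33.0 3.15002592e-03
34.0 3.87179950e-03
35.0 4.64982143e-03
36.0 5.47186835e-03
37.0 6.32526316e-03
38.0 7.19747319e-03
39.0 8.07657497e-03
40.0 8.95158790e-03
41.0 9.67303406e-03
42.0 1.03691569e-02
43.0 1.10354419e-02
44.0 1.16682909e-02
45.0 1.22649472e-02
46.0 1.28234120e-02
47.0 1.33423574e-02
48.0 1.38210396e-02
49.0 1.42592157e-02
50.0 1.46570661e-02
51.0 1.48968505e-02
52.0 1.51044705e-02
53.0 1.52812295e-02
54.0 1.54284877e-02
55.0 1.55476387e-02
56.0 1.56400902e-02
57.0 1.57072490e-02
58.0 2.50749021e-02
59.0 3.34308443e-02
60.0 1.57707619e-02
61.0 1.56944136e-02
62.0 1.56028127e-02
63.0 1.54971198e-02
64.0 1.53784289e-02
65.0 1.52477705e-02
66.0 1.51061128e-02
67.0 2.12515572e-02
68.0 1.47933783e-02
69.0 1.46239512e-02
70.0 1.44468299e-02
71.0 1.42627117e-02
72.0 1.40722479e-02
73.0 1.38760463e-02
74.0 1.36746733e-02
75.0 1.34686571e-02
76.0 1.32584891e-02
77.0 1.30446270e-02
78.0 1.28274964e-02
79.0 1.26074928e-02
80.0 1.23849840e-02
81.0 1.21298499e-02
82.0 1.18753611e-02
83.0 1.16216703e-02
84.0 1.13689158e-02
85.0 1.11172232e-02
86.0 1.08667064e-02
87.0 1.06174681e-02
88.0 1.03696011e-02
89.0 1.01231886e-02
90.0 9.87830568e-03
91.0 9.63501913e-03
92.0 9.39338863e-03
93.0 9.15346713e-03
94.0 8.91530139e-03
95.0 8.67893249e-03
96.0 8.44439625e-03
97.0 8.21172370e-03
98.0 7.98094140e-03
99.0 7.75207186e-03
100.0 7.52513380e-03
101.0 7.29250140e-03
102.0 7.06250588e-03
103.0 6.83512257e-03
104.0 6.61032584e-03
105.0 6.38808925e-03
106.0 6.16838564e-03
107.0 5.95118727e-03
108.0 5.73646589e-03
109.0 5.52419284e-03
110.0 5.31433914e-03
111.0 5.10687554e-03
112.0 4.90177260e-03
113.0 4.69900076e-03
114.0 4.49853036e-03
115.0 4.30033172e-03
116.0 4.10437520e-03
117.0 3.91063118e-03
118.0 3.71907015e-03
119.0 3.52966273e-03
120.0 3.34237969e-03
121.0 3.15719198e-03
122.0 2.97407075e-03
123.0 2.79298738e-03
124.0 2.61391350e-03
125.0 2.43682098e-03
126.0 2.26168198e-03
127.0 2.08846896e-03
128.0 1.91715464e-03
129.0 1.74771209e-03
130.0 1.58011467e-03
131.0 1.41433607e-03
132.0 1.25035030e-03
133.0 1.08813173e-03
134.0 9.27655031e-04
135.0 7.68895243e-04
136.0 6.11827736e-04
137.0 4.56428225e-04
138.0 3.02672771e-04
139.0 1.50537779e-04
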