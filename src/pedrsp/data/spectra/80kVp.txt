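# 80kVp: tungsten-anode model, 80 kVp, filters {'Al': 8.0}
10.0 1.78234840e-25
11.0 1.65466339e-19
12.0 2.35408531e-15
13.0 2.23401019e-12
14.0 3.44511879e-10
15.0 1.51254273e-08
16.0 2.65124401e-07
17.0 2.45999048e-06
18.0 1.42480836e-05
19.0 5.78554431e-05
20.0 1.79025096e-04
21.0 4.26259541e-04
22.0 8.72861852e-04
23.0 1.58422475e-03
24.0 2.60823048e-03
25.0 3.96598005e-03
26.0 5.64897986e-03
27.0 7.62206064e-03
28.0 9.82994933e-03
29.0 1.22052377e-02
30.0 1.46760021e-02
31.0 1.67131926e-02
32.0 1.86881291e-02
33.0 2.05664598e-02
34.0 2.23207890e-02
35.0 2.39304289e-02
36.0 2.53808426e-02
37.0 2.66629158e-02
38.0 2.77721585e-02
39.0 2.87079088e-02
40.0 2.94725826e-02
41.0 2.96983696e-02
42.0 2.98045601e-02
43.0 2.97988040e-02
44.0 2.96888459e-02
45.0 2.94823870e-02
46.0 2.91869784e-02
47.0 2.88099421e-02
48.0 2.83583137e-02
49.0 2.78388024e-02
50.0 2.72577663e-02
51.0 2.64581310e-02
52.0 2.56314196e-02
53.0 2.47810922e-02
54.0 2.39103248e-02
55.0 2.30220291e-02
56.0 2.21188702e-02
57.0 2.12032849e-02
58.0 2.52594460e-02
59.0 2.86023394e-02
60.0 1.84032555e-02
61.0 1.73852129e-02
62.0 1.63763135e-02
63.0 1.53769243e-02
64.0 1.43873575e-02
65.0 1.34078755e-02
66.0 1.24386964e-02
67.0 1.44948861e-02
68.0 1.05319228e-02
69.0 9.59458047e-03
70.0 8.66805220e-03
71.0 7.75239324e-03
72.0 6.84763574e-03
73.0 5.95379116e-03
74.0 5.07085253e-03
75.0 4.19879647e-03
76.0 3.33758494e-03
77.0 2.48716697e-03
78.0 1.64748007e-03
79.0 8.18451607e-04
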