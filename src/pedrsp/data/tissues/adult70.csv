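# Adult reference tissue database (70 tissues): elemental mass fractions and
# mean mass densities of standardized adult human tissues, after the published
# reference tables of Woodard & White and White et al. (soft tissues and
# resegmented skeletal sites). Best-effort transcription; note column records
# the source family per row.
tissue_id,name,age_group,sex,group,density,H,C,N,O,Na,Mg,Si,P,S,Cl,K,Ca,Fe,I,note
1,Adipose tissue 1,adult,male,soft,0.97,0.112,0.517,0.013,0.355,0.001,0,0,0,0.001,0.001,0,0,0,0,WW1986
2,Adipose tissue 2,adult,male,soft,0.95,0.114,0.598,0.007,0.278,0.001,0,0,0,0.001,0.001,0,0,0,0,WW1986
3,Adipose tissue 3,adult,male,soft,0.93,0.116,0.681,0.002,0.198,0.001,0,0,0,0.001,0.001,0,0,0,0,WW1986
4,Adrenal gland,adult,male,soft,1.03,0.106,0.284,0.026,0.578,0.001,0,0,0.001,0.002,0.002,0,0,0,0,WW1986
5,Aorta,adult,male,soft,1.05,0.099,0.147,0.042,0.698,0.002,0,0,0.004,0.003,0.001,0,0.004,0,0,WW1986
6,Blood whole,adult,male,soft,1.06,0.102,0.110,0.033,0.745,0.001,0,0,0.001,0.002,0.003,0.002,0,0.001,0,WW1986
7,Brain grey matter,adult,male,soft,1.04,0.107,0.095,0.018,0.767,0.002,0,0,0.003,0.002,0.003,0.003,0,0,0,WW1986
8,Brain white matter,adult,male,soft,1.04,0.106,0.194,0.025,0.661,0.002,0,0,0.004,0.002,0.003,0.003,0,0,0,WW1986
9,Brain whole,adult,male,soft,1.04,0.107,0.145,0.022,0.712,0.002,0,0,0.004,0.002,0.003,0.003,0,0,0,WW1986
10,Mammary gland 1,adult,female,soft,0.99,0.109,0.506,0.023,0.358,0.001,0,0,0.001,0.001,0.001,0,0,0,0,WW1986
11,Mammary gland 2,adult,female,soft,1.02,0.106,0.332,0.030,0.527,0.001,0,0,0.001,0.002,0.001,0,0,0,0,WW1986
12,Mammary gland 3,adult,female,soft,1.06,0.102,0.184,0.032,0.677,0.001,0,0,0.001,0.002,0.001,0,0,0,0,WW1986
13,Cerebrospinal fluid,adult,male,soft,1.01,0.111,0,0,0.880,0.005,0,0,0,0,0.004,0,0,0,0,WW1986
14,Eye lens,adult,male,soft,1.07,0.096,0.195,0.057,0.646,0.001,0,0,0.001,0.003,0.001,0,0,0,0,WW1986
15,Gallbladder bile,adult,male,soft,1.03,0.108,0.061,0.001,0.822,0.004,0,0,0,0,0.004,0,0,0,0,WW1986
16,GI tract stomach,adult,male,soft,1.05,0.104,0.139,0.029,0.721,0.001,0,0,0.001,0.002,0.001,0.002,0,0,0,WW1986
17,Small intestine,adult,male,soft,1.03,0.106,0.115,0.022,0.751,0.001,0,0,0.001,0.002,0.002,0,0,0,0,WW1986
18,Heart 1,adult,male,soft,1.05,0.104,0.175,0.031,0.681,0.001,0,0,0.002,0.002,0.002,0.002,0,0,0,WW1986
19,Heart 2,adult,male,soft,1.05,0.104,0.139,0.029,0.718,0.001,0,0,0.002,0.002,0.002,0.003,0,0,0,WW1986
20,Heart 3,adult,male,soft,1.06,0.104,0.103,0.027,0.756,0.001,0,0,0.002,0.002,0.002,0.003,0,0,0,WW1986
21,Heart blood-filled,adult,male,soft,1.06,0.103,0.121,0.032,0.734,0.001,0,0,0.001,0.002,0.003,0.002,0,0.001,0,WW1986
22,Kidney 1,adult,male,soft,1.05,0.102,0.160,0.034,0.693,0.002,0,0,0.002,0.002,0.002,0.002,0.001,0,0,WW1986
23,Kidney 2,adult,male,soft,1.05,0.103,0.132,0.030,0.724,0.002,0,0,0.002,0.002,0.002,0.002,0.001,0,0,WW1986
24,Kidney 3,adult,male,soft,1.05,0.104,0.106,0.027,0.752,0.002,0,0,0.002,0.002,0.002,0.002,0.001,0,0,WW1986
25,Liver 1,adult,male,soft,1.05,0.103,0.156,0.027,0.701,0.002,0,0,0.003,0.003,0.002,0.003,0,0,0,WW1986
26,Liver 2,adult,male,soft,1.06,0.102,0.139,0.030,0.716,0.002,0,0,0.003,0.003,0.002,0.003,0,0,0,WW1986
27,Liver 3,adult,male,soft,1.07,0.101,0.127,0.033,0.727,0.002,0,0,0.002,0.003,0.002,0.003,0,0,0,WW1986
28,Lung parenchyma deflated,adult,male,soft,1.05,0.103,0.105,0.031,0.749,0.002,0,0,0.002,0.003,0.003,0.002,0,0,0,WW1986
29,Lung inflated,adult,male,lung,0.26,0.103,0.105,0.031,0.749,0.002,0,0,0.002,0.003,0.003,0.002,0,0,0,WW1986
30,Lymph,adult,male,soft,1.03,0.108,0.041,0.011,0.832,0.003,0,0,0,0.001,0.004,0,0,0,0,WW1986
31,Skeletal muscle 1,adult,male,soft,1.05,0.101,0.171,0.036,0.681,0.001,0,0,0.002,0.003,0.001,0.004,0,0,0,WW1986
32,Skeletal muscle 2,adult,male,soft,1.05,0.102,0.143,0.034,0.710,0.001,0,0,0.002,0.003,0.001,0.004,0,0,0,WW1986
33,Skeletal muscle 3,adult,male,soft,1.05,0.102,0.112,0.030,0.745,0.001,0,0,0.002,0.003,0.001,0.004,0,0,0,WW1986
34,Ovary,adult,female,soft,1.05,0.105,0.093,0.024,0.768,0.002,0,0,0.002,0.002,0.002,0.002,0,0,0,WW1986
35,Pancreas,adult,male,soft,1.04,0.106,0.169,0.022,0.694,0.002,0,0,0.002,0.001,0.002,0.002,0,0,0,WW1986
36,Prostate,adult,male,soft,1.04,0.105,0.089,0.025,0.774,0.002,0,0,0.001,0.002,0.001,0.001,0,0,0,WW1986
37,Skin 1,adult,male,soft,1.09,0.100,0.250,0.046,0.595,0.002,0,0,0.001,0.002,0.003,0.001,0,0,0,WW1986
38,Skin 2,adult,male,soft,1.09,0.100,0.204,0.042,0.645,0.002,0,0,0.001,0.002,0.003,0.001,0,0,0,WW1986
39,Skin 3,adult,male,soft,1.09,0.101,0.158,0.037,0.695,0.002,0,0,0.001,0.002,0.003,0.001,0,0,0,WW1986
40,Spleen,adult,male,soft,1.06,0.103,0.113,0.032,0.741,0.001,0,0,0.003,0.002,0.002,0.003,0,0,0,WW1986
41,Testis,adult,male,soft,1.04,0.106,0.099,0.020,0.766,0.002,0,0,0.001,0.002,0.002,0.002,0,0,0,WW1986
42,Thyroid,adult,male,soft,1.05,0.104,0.119,0.024,0.745,0.002,0,0,0.001,0.001,0.002,0.001,0,0,0.001,WW1986
43,Urinary bladder wall,adult,male,soft,1.04,0.105,0.096,0.026,0.761,0.002,0,0,0.002,0.002,0.003,0.003,0,0,0,WW1986
44,Urine,adult,male,soft,1.02,0.110,0.005,0.010,0.868,0.004,0,0,0.001,0,0,0.002,0,0,0,WW1986
45,Trachea,adult,male,soft,1.06,0.101,0.139,0.033,0.713,0.001,0,0,0.004,0.004,0.002,0.003,0,0,0,WW1986
46,Thymus,adult,male,soft,1.03,0.105,0.120,0.030,0.736,0.002,0,0,0.002,0.002,0.002,0.001,0,0,0,WW1986
47,Cartilage,adult,male,soft,1.10,0.096,0.099,0.022,0.744,0.005,0,0,0.022,0.009,0.003,0,0,0,0,WW1986
48,Cortical bone,adult,male,bone,1.92,0.034,0.155,0.042,0.435,0.001,0.002,0,0.103,0.003,0,0,0.225,0,0,WWH1987
49,Spongiosa whole skeleton,adult,male,bone,1.18,0.085,0.404,0.028,0.367,0.002,0.001,0,0.034,0.002,0.002,0.001,0.073,0.001,0,WWH1987
50,Red marrow,adult,male,soft,1.03,0.105,0.414,0.034,0.439,0,0,0,0.001,0.002,0.002,0.002,0,0.001,0,WW1986
51,Yellow marrow,adult,male,soft,0.98,0.115,0.644,0.007,0.231,0.001,0,0,0,0.001,0.001,0,0,0,0,WW1986
52,Cranium,adult,male,bone,1.61,0.050,0.212,0.040,0.435,0.001,0.002,0,0.081,0.003,0,0,0.176,0,0,WWH1987
53,Mandible,adult,male,bone,1.68,0.046,0.199,0.041,0.435,0.001,0.002,0,0.086,0.003,0,0,0.187,0,0,WWH1987
54,Femur whole,adult,male,bone,1.33,0.070,0.345,0.028,0.368,0.001,0.001,0,0.055,0.002,0.001,0,0.129,0,0,WWH1987
55,Humerus whole,adult,male,bone,1.46,0.060,0.314,0.031,0.369,0.001,0.001,0,0.070,0.002,0,0,0.152,0,0,WWH1987
56,Ribs 2nd and 6th,adult,male,bone,1.41,0.064,0.263,0.039,0.436,0.001,0.001,0,0.060,0.003,0.001,0.001,0.131,0,0,WWH1987
57,Ribs 10th,adult,male,bone,1.52,0.056,0.235,0.040,0.434,0.001,0.001,0,0.072,0.003,0.001,0.001,0.156,0,0,WWH1987
58,Sacrum,adult,male,bone,1.29,0.074,0.302,0.037,0.438,0.001,0.001,0,0.045,0.002,0.001,0.001,0.098,0,0,WWH1987
59,Cervical vertebra C4,adult,male,bone,1.42,0.063,0.261,0.039,0.436,0.001,0.001,0,0.061,0.003,0.001,0.001,0.133,0,0,WWH1987
60,Vertebrae D6 L3,adult,male,bone,1.30,0.070,0.287,0.038,0.437,0.001,0.001,0,0.051,0.002,0.001,0.001,0.111,0,0,WWH1987
61,Innominate,adult,male,bone,1.41,0.063,0.262,0.039,0.436,0.001,0.001,0,0.061,0.003,0.001,0.001,0.132,0,0,WWH1987
62,Clavicle scapula,adult,male,bone,1.46,0.061,0.309,0.032,0.372,0.001,0.001,0,0.069,0.002,0,0,0.153,0,0,WWH1987
63,Connective tissue,adult,male,soft,1.12,0.094,0.207,0.062,0.622,0.006,0,0,0,0.006,0.003,0,0,0,0,WW1986
64,Eyes whole,adult,male,soft,1.05,0.097,0.183,0.053,0.660,0.001,0,0,0.001,0.003,0.001,0.001,0,0,0,WW1986
65,Oesophagus,adult,male,soft,1.03,0.104,0.139,0.029,0.722,0.001,0,0,0.001,0.002,0.001,0.001,0,0,0,WW1986
66,Pituitary gland,adult,male,soft,1.03,0.106,0.119,0.024,0.745,0.001,0,0,0.001,0.002,0.001,0.001,0,0,0,WW1986
67,Humerus spherical head,adult,male,bone,1.36,0.068,0.332,0.029,0.376,0.001,0.001,0,0.058,0.002,0,0,0.133,0,0,WWH1987
68,Femur cylindrical shaft,adult,male,bone,1.75,0.042,0.204,0.038,0.415,0.001,0.002,0,0.093,0.003,0,0,0.202,0,0,WWH1987
69,Sternum,adult,male,bone,1.25,0.078,0.317,0.037,0.438,0.001,0.001,0,0.040,0.002,0.001,0.001,0.084,0,0,WWH1987
70,Spinal cord,adult,male,soft,1.04,0.106,0.194,0.025,0.661,0.002,0,0,0.004,0.002,0.003,0.003,0,0,0,WW1986
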