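# Gammex RMI 467 electron-density phantom insert compositions and densities,
# after the published vendor-derived table of Bourque et al. Water is the
# reference insert. Mass fractions; epoxy lung surrogates contain Mg and Si.
tissue_id,name,age_group,sex,group,density,H,C,N,O,Na,Mg,Si,P,S,Cl,K,Ca,Fe,I,note
1,LN-300 Lung,adult,male,lung,0.30,0.0846,0.5938,0.0196,0.1814,0,0.1119,0.0078,0,0,0.0010,0,0,0,0,Bourque2014
2,LN-450 Lung,adult,male,lung,0.45,0.0847,0.5956,0.0197,0.1811,0,0.1121,0.0058,0,0,0.0010,0,0,0,0,Bourque2014
3,AP6 Adipose,adult,male,soft,0.92,0.0906,0.7230,0.0225,0.1627,0,0,0,0,0,0.0013,0,0,0,0,Bourque2014
4,BR-12 Breast,adult,male,soft,0.98,0.0859,0.7011,0.0233,0.1790,0,0,0,0,0,0.0013,0,0.0095,0,0,Bourque2014
5,CT Solid Water,adult,male,soft,1.015,0.0800,0.6729,0.0239,0.1987,0,0,0,0,0,0.0014,0,0.0231,0,0,Bourque2014
6,Water,adult,male,soft,1.000,0.1119,0,0,0.8881,0,0,0,0,0,0,0,0,0,0,reference
7,SR2 Brain,adult,male,soft,1.049,0.1083,0.7254,0.0169,0.1486,0,0,0,0,0,0.0008,0,0,0,0,Bourque2014
8,LV1 Liver,adult,male,soft,1.08,0.0806,0.6701,0.0247,0.2001,0,0,0,0,0,0.0014,0,0.0231,0,0,Bourque2014
9,B200 Bone mineral,adult,male,bone,1.152,0.0665,0.5551,0.0198,0.2364,0,0,0,0.0324,0,0.0011,0,0.0887,0,0,Bourque2014
10,IB3 Inner bone,adult,male,bone,1.133,0.0667,0.5564,0.0196,0.2352,0,0,0,0.0323,0,0.0011,0,0.0887,0,0,Bourque2014
11,CB2-30 Resin,adult,male,bone,1.335,0.0668,0.5348,0.0212,0.2561,0,0,0,0,0,0.0011,0,0.1200,0,0,Bourque2014
12,CB2-50 Resin,adult,male,bone,1.560,0.0477,0.4163,0.0152,0.3199,0,0,0,0,0,0.0008,0,0.2001,0,0,Bourque2014
13,SB3 Cortical bone,adult,male,bone,1.819,0.0341,0.3141,0.0184,0.3650,0,0,0,0,0,0.0004,0,0.2680,0,0,Bourque2014
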