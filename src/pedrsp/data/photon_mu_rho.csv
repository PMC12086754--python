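# Total mass attenuation coefficients with coherent scattering, cm^2/g.
# Transcribed XCOM-style point values on a 10-150 keV grid for the elements
# abundant in human tissue, plus Si (phantom epoxy inserts) and the filter
# metals Al and Sn used in spectrum generation. Iodine and tin carry extra
# grid points bracketing their K absorption edges (33.17 and 29.20 keV).
symbol,energy_keV,mu_rho
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.3570
H,40,0.3458
H,50,0.3355
H,60,0.3260
H,80,0.3091
H,100,0.2944
H,150,0.2651
C,10,2.373
C,15,0.8071
C,20,0.4420
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.1610
C,100,0.1514
C,150,0.1347
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.1980
N,60,0.1817
N,80,0.1639
N,100,0.1529
N,150,0.1353
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
O,100,0.1551
O,150,0.1361
Na,10,15.14
Na,15,4.694
Na,20,2.057
Na,30,0.7197
Na,40,0.3969
Na,50,0.2804
Na,60,0.2268
Na,80,0.1796
Na,100,0.1585
Na,150,0.1335
Mg,10,20.76
Mg,15,6.358
Mg,20,2.763
Mg,30,0.9306
Mg,40,0.4881
Mg,50,0.3292
Mg,60,0.2570
Mg,80,0.1951
Mg,100,0.1686
Mg,150,0.1394
Al,10,26.23
Al,15,7.955
Al,20,3.441
Al,30,1.128
Al,40,0.5685
Al,50,0.3681
Al,60,0.2778
Al,80,0.2018
Al,100,0.1704
Al,150,0.1378
Si,10,33.89
Si,15,10.34
Si,20,4.464
Si,30,1.436
Si,40,0.6978
Si,50,0.4385
Si,60,0.3240
Si,80,0.2251
Si,100,0.1837
Si,150,0.1436
P,10,40.27
P,15,12.45
P,20,5.443
P,30,1.700
P,40,0.8096
P,50,0.4916
P,60,0.3494
P,80,0.2324
P,100,0.1865
P,150,0.1420
S,10,50.12
S,15,15.57
S,20,6.823
S,30,2.113
S,40,0.9874
S,50,0.5849
S,60,0.4053
S,80,0.2586
S,100,0.2020
S,150,0.1478
Cl,10,57.97
Cl,15,18.17
Cl,20,7.986
Cl,30,2.467
Cl,40,1.133
Cl,50,0.6614
Cl,60,0.4497
Cl,80,0.2766
Cl,100,0.2113
Cl,150,0.1489
K,10,79.06
K,15,24.73
K,20,10.87
K,30,3.315
K,40,1.492
K,50,0.8457
K,60,0.5577
K,80,0.3222
K,100,0.2351
K,150,0.1558
Ca,10,93.41
Ca,15,29.45
Ca,20,12.97
Ca,30,3.969
Ca,40,1.779
Ca,50,0.9965
Ca,60,0.6467
Ca,80,0.3619
Ca,100,0.2570
Ca,150,0.1619
Fe,10,170.6
Fe,15,57.08
Fe,20,25.68
Fe,30,8.176
Fe,40,3.629
Fe,50,1.958
Fe,60,1.205
Fe,80,0.5952
Fe,100,0.3717
Fe,150,0.1964
Sn,10,21.00
Sn,15,7.120
Sn,20,3.290
Sn,25,1.840
Sn,29.0,1.240
Sn,29.35,7.000
Sn,30,6.550
Sn,40,3.080
Sn,50,1.750
Sn,60,1.140
Sn,80,0.5600
Sn,100,0.3460
Sn,150,0.1563
I,10,26.32
I,15,8.930
I,20,4.089
I,30,1.389
I,33.0,1.100
I,33.3,6.200
I,40,3.950
I,50,2.240
I,60,1.440
I,80,0.6860
I,100,0.4278
I,150,0.1881
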