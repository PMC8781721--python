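run_id,TPC,TFC,ABTS,DPPH,FRAP
1,1280,925,74,95,319
2,1644,1015,83,136,364
3,603,692,25,49,150
4,811,700,25,82,130
5,1593,1203,88,113,443
6,1677,1207,101,163,448
7,731,867,34,65,180
8,850,877,37,96,246
9,1231,847,58,105,289
10,1986,1513,109,162,504
11,1315,906,74,126,348
12,525,646,9,51,119
13,1075,1121,61,71,321
14,1652,1038,74,160,442
15,1479,1055,73,121,316
16,1379,1087,72,125,346
17,1405,1186,77,128,364
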