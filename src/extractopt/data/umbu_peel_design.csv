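run_id,block,temperature_real,ethanol_real,solid_liquid_real
1,factorial,40,30,20
2,factorial,40,30,50
3,factorial,40,80,20
4,factorial,40,80,50
5,factorial,65,30,20
6,factorial,65,30,50
7,factorial,65,80,20
8,factorial,65,80,50
9,axial,32,55,35
10,axial,74,55,35
11,axial,53,13,35
12,axial,53,97,35
13,axial,53,55,10
14,axial,53,55,60
15,center,53,55,35
16,center,53,55,35
17,center,53,55,35
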