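id,ion_mode,rt_min,mz_observed,mz_theoretical,formula,adduct,metabolite
1,negative,4.14,153.0200,153.0193,C7H6O4,[M-H]-,"3,5-Dihydroxybenzoic acid"
2,negative,18.45,609.1482,609.1461,C27H30O16,[M-H]-,Rutin
3,negative,18.72,463.0862,463.0882,C21H20O12,[M-H]-,Isoquercitrin
4,negative,20.62,593.1535,593.1512,C27H30O15,[M-H]-,Kaempferol 3-O-rutinoside
5,negative,35.27,193.0709,193.0506,C10H10O4,[M-H]-,Ferulic acid
6,positive,1.58,325.1329,325.1129,C12H22O11,[M-H2O+H]+,Sucrose
7,positive,3.10,130.0863,130.0863,C6H11NO2,[M+H]+,Pipecolic acid
8,positive,7.47,165.0545,165.0546,C9H8O3,[M+H]+,Coumaric acid
9,positive,7.82,347.1670,347.1337,C15H22O9,[M+H]+,Koaburside
10,positive,9.62,138.0557,138.0550,C7H7NO2,[M+H]+,Anthranilic acid
2,positive,18.40,611.1614,611.1607,C27H30O16,[M+H]+,Rutin
3,positive,18.54,465.1028,465.1028,C21H20O12,[M+H]+,Isoquercitrin
11,positive,19.42,167.0705,167.0703,C9H10O3,[M+H]+,2'-Hydroxy-4'-methoxyacetophenone
12,positive,36.01,205.1166,205.1223,C13H16O2,[M+H]+,4-Acetyl-2-prenylphenol
13,positive,36.11,581.1551,581.1501,C26H28O15,[M+H]+,Quercetin-deoxyhexosyl-pentoside
14,positive,38.09,389.2336,389.0843,C17H18O9,[M+Na]+,Rubinaphthin A
15,positive,42.19,197.0812,197.0808,C10H12O4,[M+H]+,Dihydroferulic acid
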