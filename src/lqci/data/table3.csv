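Year,U,GDPGR,PS,PGR,CA,SD,VCR,FCR,FA,GRBA,GSPC,WA,TWR,AA,BD,RND,CPN
2015,76.00,8.50,87.56,2.30,422.00,1221.60,22,17.00,1.45,50.00,1.06,598,2.36,0.14,24.00,1.91,8
2016,76.85,8.40,90.69,4.38,597.70,1274.20,35,26.00,1.43,49.20,2.30,598,2.31,0.15,25.00,1.94,8
2017,77.71,9.30,92.87,4.00,597.00,1263.50,35,28.60,1.44,48.00,2.25,598,2.29,0.17,25.00,1.98,8
2018,78.75,5.70,94.72,6.50,554.00,1287.60,36,28.30,1.45,40.00,2.10,598,2.68,0.18,24.00,1.98,10
2019,81.47,8.90,96.10,4.00,597.00,1298.10,35,28.00,1.45,37.51,2.19,598,2.79,0.18,25.00,2.13,10
2020,80.25,4.90,129.85,4.13,597.30,1257.80,36,28.34,1.45,38.27,1.61,598,2.84,1.68,24.00,2.40,10
2021,74.30,9.00,131.03,4.13,554.47,1269.80,36,28.30,1.23,37.00,1.48,598,2.21,1.68,22.57,2.34,12
2022,82.00,5.00,131.03,3.15,564.12,1289.70,35,36.10,1.52,37.89,1.53,598,3.53,1.68,23.00,2.45,12
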