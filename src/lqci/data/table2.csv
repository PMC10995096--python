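id,code,abbrev,name,layer,group,weight_percent
1,U,U,Urbanization,SEI,,0.907
2,PS,PS,Population scale,SEI,,2.151
3,PGR,PGR,Population growth ratio,SEI,,0.601
4,GDP,GDP,Gross domestic product,SEI,,2.222
5,GDPGR,GDPGR,GDP growth ratio,SEI,,0.622
6,BD,BD,Building density,SEI,,0.693
7,RND,RND,Road network density,SEI,,1.369
8,PN,PN,Park number,SEI,,1.102
9,SD,SD,Sunshine duration,EEI,,2.471
10,AA,AA,Arable area,EEI,,1.547
11,WA,WA,Water area,EEI,,2.293
12,TWR,TWR,Total water resources,EEI,,1.511
13,WRPC,WRPC,Water resources per capita,EEI,,2.187
14,FCR,FCR,Forest cover ratio,EEI,,1.511
15,GRBA,GRBA,Greening rate in built-up area,EEI,,0.764
16,GSPC,GSPC,Green space per capita,EEI,,1.689
17,CPN,CPN,City park number,EEI,,2.634
18,NP_G,NP,Number of plaques,LPCI,vegetation,4.494
19,DP_G,DP,Density of plaques,LPCI,vegetation,2.841
20,AREA_MN_G,AREA MN,Average plaque size,LPCI,vegetation,1.188
21,LPI_G,LPI,Largest plaque index,LPCI,vegetation,0.981
22,LSI_G,LSI,Landscape shape index,LPCI,vegetation,3.771
23,AI_G,AI,Plaque aggregation,LPCI,vegetation,3.461
24,NP_W,NP,Number of plaques,LPCI,water,3.564
25,DP_W,DP,Density of plaques,LPCI,water,0.465
26,AREA_MN_W,AREA MN,Average plaque size,LPCI,water,2.324
27,LPI_W,LPI,Largest Plaque Index,LPCI,water,0.671
28,LSI_W,LSI,Landscape Shape Index,LPCI,water,2.738
29,AI_W,AI,Plaque aggregation,LPCI,water,3.151
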