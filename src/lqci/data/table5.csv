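year,class,np,pd,lpi,lsi,area_mn,ai
2015,green,175,0.3146,0.1854,29.6322,26.9731,72.0555
2015,water,46,0.0827,2.1345,12.8114,42.9163,91.9491
2016,green,677,0.020,0.0552,34.7467,91.1041,51.8140
2016,water,748,0.0100,0.3847,21.3263,2.0802,37.4000
2017,green,708,0.020,0.0527,35.2432,50.9912,70.4596
2017,water,720,0.0100,0.3842,21.0360,2.1230,24.4731
2018,green,664,0.020,0.0471,33.6292,1.0004,63.8600
2018,water,696,0.0100,0.3852,20.7032,2.1735,27.4731
2019,green,567,0.020,0.0423,33.4561,1.0012,64.9501
2019,water,656,0.0100,0.3719,20.8791,2.1678,27.4512
2020,green,172,0.3092,3.0134,20.0533,68.2914,75.7685
2020,water,34,0.0611,2.9726,12.5533,59.5085,92.2395
2021,green,26432,21.87,0.3210,254.321,0.8282,81.4021
2021,water,215,0.1623,0.3123,18.7456,6.0432,95.2010
2022,green,29565,21.991,0.4006,273.5354,0.8445,81.4137
2022,water,229,0.1703,0.3224,19.1082,6.4152,95.2605
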