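year,truth_lqci,bp_pred,gabp_pred,level
2015,28.77,29.4074,28.3763,IV
2016,35.65,35.6488,35.2576,III
2017,36.25,35.0981,35.9475,III
2018,37.23,37.2289,38.2652,II
2019,36.69,34.6001,36.7376,II
2020,40.27,40.2912,40.1617,I
2021,42.34,42.3212,42.4046,I
2022,43.72,36.6588,41.4849,I
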