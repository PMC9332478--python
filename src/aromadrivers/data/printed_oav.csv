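compound_id,B1,B2,B3,B4,B5,B6
1,26.130,125.103,156.666,114.390,60.834,93.584
2,118.177,170.431,173.433,22.156,22.386,227.178
4,11.220,1.914,,9.659,4.218,7.165
7,14.479,123.443,69.205,12.564,13.876,263.524
8,41.605,12.813,,46.109,73.764,2.244
9,,,,,5.698,
14,,1.905,,2.080,,
15,4154.525,3420.799,4034.055,5790.261,3526.653,3075.922
19,3645.795,3208.173,5195.313,2781.376,5331.364,2762.692
20,,4.165,1.221,,,25.182
21,,,,,3.679,
22,,,,,1.133,
23,191.887,119.274,97.302,136.356,233.104,72.358
24,3.993,7.174,5.834,2.927,9.514,1.403
27,,,,,1.067,
28,613.975,194.026,102.920,753.580,927.503,231.874
29,,49.359,,17.635,2.641,66.542
30,21.738,86.984,16.267,19.342,18.783,1.986
32,65.961,2017.506,241.127,28.278,38.555,60.044
37,,2.433,1.723,,,
39,15.642,245.762,20.371,7.726,,
43,7.372,19.470,4.672,8.375,9.111,6.361
46,16.181,63.629,52.470,29.662,3.817,
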