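compound_id,sample,mean,sd,flag,letters
1,B1,130650.99,6636.18,OK,a
1,B2,625514.35,1291.87,OK,e
1,B3,783331.79,6806.85,OK,f
1,B4,571951.58,3619.70,OK,d
1,B5,304167.86,5632.55,OK,b
1,B6,467917.75,8154.52,OK,c
2,B1,1181.77,4.53,OK,b
2,B2,1704.31,14.55,OK,c
2,B3,1734.33,10.94,OK,c
2,B4,221.56,8.28,OK,a
2,B5,223.86,4.31,OK,a
2,B6,2271.78,47.05,OK,d
3,B1,751.54,38.69,OK,a
3,B2,5244.03,76.36,OK,c
3,B3,399.66,23.07,OK,a
3,B4,2123.75,34.38,OK,b
3,B5,1792.44,61.09,OK,b
3,B6,812.39,536.96,OK,a
4,B1,740.49,7.53,OK,f
4,B2,126.34,1.17,OK,b
4,B3,16.24,0.18,OK,a
4,B4,637.52,6.18,OK,e
4,B5,278.41,2.77,OK,c
4,B6,472.90,30.91,OK,d
5,B1,21239.27,78.78,OK,d
5,B2,3100.82,47.47,OK,a
5,B3,,,TRACE,
5,B4,22149.40,183.22,OK,e
5,B5,7331.81,70.42,OK,b
5,B6,11597.80,2340.62,OK,c
6,B1,344314.42,3037.80,OK,d
6,B2,8624.00,193.86,OK,ab
6,B3,208404.31,1309.92,OK,c
6,B4,6464.71,627.42,OK,a
6,B5,8724.21,206.27,OK,ab
6,B6,11842.14,825.47,OK,b
7,B1,159.27,6.92,OK,a
7,B2,1357.87,113.19,OK,c
7,B3,761.25,39.64,OK,b
7,B4,138.21,18.20,OK,a
7,B5,152.63,2.70,OK,a
7,B6,2898.76,2.70,OK,d
8,B1,2496.29,5.54,OK,d
8,B2,768.78,3.38,OK,c
8,B3,57.64,15.06,OK,a
8,B4,2766.54,4.32,OK,e
8,B5,4425.84,3.75,OK,f
8,B6,134.63,36.13,OK,b
9,B1,607.73,1.70,OK,a
9,B2,1786.03,57.56,OK,c
9,B3,1354.23,92.26,OK,b
9,B4,1881.49,200.04,OK,d
9,B5,11395.23,347.24,OK,e
9,B6,,,TRACE,
10,B1,,,TRACE,
10,B2,,,TRACE,
10,B3,,,TRACE,
10,B4,,,TRACE,
10,B5,,,TRACE,
10,B6,,,TRACE,
11,B1,0.45,0.19,OK,b
11,B2,,,TRACE,
11,B3,,,TRACE,
11,B4,0.62,0.16,OK,b
11,B5,1.47,0.30,OK,c
11,B6,,,TRACE,
12,B1,39262.87,58.38,OK,e
12,B2,22572.34,19.84,OK,c
12,B3,19246.37,27.46,OK,b
12,B4,35396.43,20.06,OK,d
12,B5,44409.15,95.67,OK,f
12,B6,3022.45,337.71,OK,a
13,B1,,,TRACE,
13,B2,,,TRACE,
13,B3,,,TRACE,
13,B4,,,TRACE,
13,B5,,,TRACE,
13,B6,,,TRACE,
14,B1,1150.98,2.29,OK,a
14,B2,6667.33,10.79,OK,e
14,B3,2167.45,12.54,OK,b
14,B4,7281.14,0.96,OK,f
14,B5,2704.11,11.99,OK,c
14,B6,3383.24,156.20,OK,d
15,B1,16618.10,34.91,OK,c
15,B2,13683.19,2.56,OK,b
15,B3,16136.22,62.54,OK,c
15,B4,23161.05,76.12,OK,d
15,B5,14106.61,38.35,OK,b
15,B6,12303.69,556.86,OK,a
16,B1,1982.62,135.83,OK,b
16,B2,14611.62,877.44,OK,d
16,B3,7735.74,1024.88,OK,c
16,B4,1439.58,89.46,OK,ab
16,B5,2466.34,16.66,OK,b
16,B6,223.47,7.66,OK,a
17,B1,,,TRACE,
17,B2,,,TRACE,
17,B3,,,TRACE,
17,B4,,,TRACE,
17,B5,,,TRACE,
17,B6,,,TRACE,
18,B1,36.40,2.62,OK,a
18,B2,135.69,7.68,OK,a
18,B3,489.55,108.62,OK,b
18,B4,27.11,1.55,OK,a
18,B5,92.43,2.28,OK,a
18,B6,14.36,2.46,OK,a
19,B1,8020749.17,2250142.09,OK,a
19,B2,7057979.52,1329019.25,OK,a
19,B3,11429688.79,3499562.07,OK,a
19,B4,6119026.91,530020.51,OK,a
19,B5,11729001.22,5750084.35,OK,a
19,B6,6077922.73,124119.42,OK,a
20,B1,13954.14,125.32,OK,a
20,B2,83294.53,427.16,OK,c
20,B3,24429.37,153.02,OK,b
20,B4,,,TRACE,
20,B5,,,TRACE,
20,B6,503640.81,153772.98,OK,d
21,B1,73.83,0.16,OK,ab
21,B2,155.64,0.25,OK,bc
21,B3,230.41,35.27,OK,c
21,B4,46.56,0.31,OK,a
21,B5,882.92,73.08,OK,d
21,B6,40.22,0.13,OK,a
22,B1,363.08,0.08,OK,c
22,B2,397.24,17.93,OK,c
22,B3,246.81,0.38,OK,b
22,B4,379.70,23.62,OK,c
22,B5,793.42,0.05,OK,d
22,B6,137.08,23.54,OK,a
23,B1,13432.09,390.75,OK,d
23,B2,8349.21,731.17,OK,bc
23,B3,6811.15,137.18,OK,ab
23,B4,9544.95,925.82,OK,c
23,B5,16317.27,1529.55,OK,e
23,B6,5065.04,633.79,OK,a
24,B1,11979.79,5.92,OK,c
24,B2,21522.27,328.98,OK,e
24,B3,17502.03,33.56,OK,d
24,B4,8781.48,980.37,OK,b
24,B5,28541.34,986.88,OK,f
24,B6,4208.75,13.15,OK,a
25,B1,,,TRACE,
25,B2,,,TRACE,
25,B3,,,TRACE,
25,B4,,,TRACE,
25,B5,,,TRACE,
25,B6,,,TRACE,
26,B1,8637.39,32.20,OK,c
26,B2,440.01,39.83,OK,a
26,B3,,,TRACE,
26,B4,13010.93,167.42,OK,d
26,B5,4574.55,42.91,OK,b
26,B6,4819.93,1259.78,OK,b
27,B1,44617.93,137.00,OK,a
27,B2,95440.55,28644.95,OK,bc
27,B3,49629.19,601.14,OK,ab
27,B4,20513.18,528.50,OK,a
27,B5,106686.91,181.98,OK,c
27,B6,92842.65,31051.35,OK,bc
28,B1,460480.92,5729.13,OK,c
28,B2,145519.63,11269.22,OK,ab
28,B3,77189.78,7544.10,OK,a
28,B4,565184.73,42979.58,OK,d
28,B5,695627.22,40986.21,OK,e
28,B6,173905.87,24280.65,OK,b
29,B1,,,TRACE,
29,B2,6910.25,1724.70,OK,bc
29,B3,136.94,133.61,OK,ab
29,B4,2468.94,521.10,OK,abc
29,B5,369.80,283.54,OK,ab
29,B6,9315.87,5955.46,OK,c
30,B1,1412.94,5.75,OK,b
30,B2,5653.94,331.67,OK,c
30,B3,1057.34,9.49,OK,b
30,B4,1257.21,9.80,OK,b
30,B5,1220.89,5.24,OK,b
30,B6,129.10,1.78,OK,a
31,B1,285.25,29.00,OK,ab
31,B2,769.83,101.22,OK,c
31,B3,185.04,24.28,OK,a
31,B4,328.93,13.26,OK,b
31,B5,362.42,23.59,OK,b
31,B6,250.98,57.63,OK,ab
32,B1,1385.18,5.38,OK,a
32,B2,42367.62,1490.59,OK,c
32,B3,5063.67,6.19,OK,b
32,B4,593.83,117.46,OK,a
32,B5,809.65,31.79,OK,a
32,B6,1260.93,244.56,OK,a
33,B1,,,TRACE,
33,B2,,,TRACE,
33,B3,,,TRACE,
33,B4,,,TRACE,
33,B5,,,TRACE,
33,B6,,,TRACE,
34,B1,1836.67,125.52,OK,b
34,B2,10330.78,422.46,OK,e
34,B3,413.50,63.52,OK,a
34,B4,4746.59,87.82,OK,d
34,B5,199.59,15.38,OK,a
34,B6,2794.37,656.28,OK,c
35,B1,23.19,1.27,OK,a
35,B2,2829.93,226.93,OK,b
35,B3,180.21,15.24,OK,a
35,B4,14.55,0.59,OK,a
35,B5,18.91,0.36,OK,a
35,B6,30.89,6.62,OK,a
36,B1,334.34,3.85,OK,c
36,B2,1502.79,54.64,OK,f
36,B3,142.65,11.07,OK,b
36,B4,514.31,4.86,OK,d
36,B5,1057.21,8.29,OK,e
36,B6,,,TRACE,
37,B1,4810.83,49.30,OK,b
37,B2,24330.76,282.79,OK,e
37,B3,17231.94,407.93,OK,d
37,B4,5400.72,58.23,OK,b
37,B5,9834.93,152.36,OK,c
37,B6,3161.14,549.63,OK,a
38,B1,19300.71,1153.50,OK,e
38,B2,15329.97,1124.08,OK,d
38,B3,8932.46,178.69,OK,b
38,B4,18218.52,51.99,OK,e
38,B5,12829.97,133.62,OK,c
38,B6,965.43,193.69,OK,a
39,B1,93.85,0.52,OK,b
39,B2,1474.57,75.16,OK,c
39,B3,122.23,11.09,OK,b
39,B4,46.35,0.08,OK,ab
39,B5,2.39,0.45,OK,a
39,B6,,,TRACE,
40,B1,1274.10,0.29,OK,c
40,B2,787.66,50.90,OK,b
40,B3,2064.35,128.89,OK,d
40,B4,1293.57,93.83,OK,c
40,B5,711.91,0.28,OK,b
40,B6,,,TRACE,
41,B1,135.85,0.72,OK,a
41,B2,4078.41,326.13,OK,c
41,B3,502.77,0.71,OK,b
41,B4,64.87,5.68,OK,a
41,B5,84.82,9.87,OK,a
41,B6,124.02,24.02,OK,a
42,B1,785.24,9.04,OK,d
42,B2,1809.90,16.33,OK,f
42,B3,1156.85,3.01,OK,e
42,B4,323.94,8.20,OK,b
42,B5,393.02,26.61,OK,c
42,B6,93.58,38.26,OK,a
43,B1,479.21,43.10,OK,ab
43,B2,1265.54,185.14,OK,c
43,B3,303.70,35.28,OK,a
43,B4,544.40,19.80,OK,b
43,B5,592.24,33.21,OK,b
43,B6,413.46,82.58,OK,ab
44,B1,,,TRACE,
44,B2,,,TRACE,
44,B3,,,TRACE,
44,B4,,,TRACE,
44,B5,,,TRACE,
44,B6,,,TRACE,
45,B1,297.71,2.71,OK,b
45,B2,3190.07,127.80,OK,e
45,B3,1498.79,10.60,OK,d
45,B4,627.20,83.01,OK,c
45,B5,91.46,13.13,OK,a
45,B6,45.30,4.69,OK,a
46,B1,29125.40,294.08,OK,b
46,B2,114532.53,1137.68,OK,e
46,B3,94445.64,2367.40,OK,d
46,B4,53390.76,5265.10,OK,c
46,B5,6870.70,140.14,OK,a
46,B6,911.37,106.41,OK,a
47,B1,1780.01,3.98,OK,c
47,B2,3373.76,15.08,OK,d
47,B3,1324.12,9.50,OK,b
47,B4,5712.76,55.65,OK,e
47,B5,8207.16,33.79,OK,f
47,B6,1020.24,43.86,OK,a
48,B1,,,TRACE,
48,B2,,,TRACE,
48,B3,,,TRACE,
48,B4,,,TRACE,
48,B5,,,TRACE,
48,B6,,,TRACE,
49,B1,1.26,0.01,OK,a
49,B2,3.48,0.01,OK,a
49,B3,3.42,1.87,OK,a
49,B4,0.92,0.21,OK,a
49,B5,0.79,0.12,OK,a
49,B6,27.83,10.31,OK,b
50,B1,70.87,0.62,OK,ab
50,B2,120.71,1.83,OK,ab
50,B3,612.06,342.68,OK,bc
50,B4,51.49,3.51,OK,a
50,B5,161.21,37.54,OK,ab
50,B6,924.48,344.18,OK,c
51,B1,1172.28,1876.58,OK,a
51,B2,2650.75,1886.25,OK,a
51,B3,323.81,252.06,OK,a
51,B4,324.17,494.20,OK,a
51,B5,829.70,296.07,OK,a
51,B6,512.85,12.92,OK,a
52,B1,12375.86,1661.42,OK,c
52,B2,4469.58,1100.56,OK,b
52,B3,1962.65,378.17,OK,a
52,B4,1414.54,16.80,OK,a
52,B5,2734.43,312.57,OK,ab
52,B6,756.57,157.68,OK,a
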