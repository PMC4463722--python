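entry,query_loel,analog1_loel,analog2_loel,analog3_loel,printed_pred,printed_fold
1,30,50,625,1.2,225.40,7.51
2,50,30,625,1.2,218.73,4.37
3,200,100,750,150,333.33,1.67
4,10,10,250,30,96.67,9.67
5,30,20,30,30,26.67,1.12
6,70,300,20,20,113.33,1.62
7,5,150,200,6,118.67,23.73
8,100,200,750,200,383.33,3.83
9,150,200,100,30,110.00,1.36
10,1000,1000,11,100,370.33,2.70
11,30,1000,100,150,416.67,13.89
12,0.75,5,6,50,20.33,27.11
13,30,20,200,10,76.67,2.56
14,3130,1000,100,600,566.67,1.84
15,100,300,750,40,363.33,3.63
16,10,10,250,30,96.67,9.67
17,30,60,60,50,56.67,1.89
18,1000,30,1000,1000,676.67,1.47
19,60,30,60,50,46.67,1.29
20,600,3130,160,62.5,1117.50,1.86
21,20,30,200,10,80.00,4.00
22,750,1000,100,200,433.33,1.73
23,25,30,250,10,96.67,3.87
24,200,300,100,750,383.33,1.92
25,1000,3130,100,100,1110.00,1.11
26,250,200,3130,70,1133.33,4.53
27,200,30,20,200,83.33,2.40
28,300,200,200,100,166.67,1.80
29,160,600,1000,1000,866.67,5.42
30,350,1000,625,625,750.00,2.14
31,60,200,750,40,330.00,5.50
32,100,240,250,10,166.67,1.67
33,100,200,100,1000,433.33,4.33
34,30,30,30,100,53.33,1.78
35,3130,2500,10,350,953.33,1.09
36,1000,1000,11,30,347.00,2.88
37,40,30,60,60,50.00,1.25
38,100,40,20,30,30.00,1.11
39,1000,750,100,100,316.67,1.05
40,300,70,20,250,113.33,2.65
41,200,150,100,30,93.33,2.14
42,30,100,300,200,200.00,6.67
43,30,30,20,30,26.67,1.12
44,5,10,3130,2500,1880.00,376.00
45,40,100,300,1000,466.67,11.67
46,2,20,30,30,26.67,13.33
47,1.2,30,625,500,385.00,320.83
48,240,100,250,10,120.00,2
49,6,11,100,150,87.00,14.50
50,250,100,240,40,126.67,1.97
51,11,1000,6,1000,668.67,60.79
52,2,30,1000,30,353.33,176.67
53,62.5,6,600,3130,1245.33,19.93
54,100,1000,1000,300,766.67,7.67
55,40,200,100,150,150.00,3.75
56,10,200,100,200,166.67,16.67
57,20,70,300,1000,456.67,22.83
58,200,300,100,100,166.67,1.20
59,300,100,1000,40,380.00,1.27
60,100,1000,30,1000,676.67,6.77
61,30,30,1000,0.78,343.59,11.45
62,20,70,20,300,130.00,6.50
63,20,30,30,100,53.33,2.67
64,30,100,150,30,93.33,3.11
65,500,250,1.2,10,87.07,1.91
66,200,781,40,60,293.67,1.47
67,1000,1000,100,240,446.67,2.23
68,625,1.2,30,60,30.40,6.85
69,10,2500,3130,1000,2210.00,221.00
70,2500,10,3130,1000,1380.00,1.81
71,100,100,150,30,93.33,1.07
72,60,30,60,50,46.67,1.29
73,50,30,60,60,50.00,1.00
74,1000,350,1000,30,460.00,2.17
75,625,625,625,350,533.33,1.17
76,0.78,350,625,625,533.33,683.76
77,40,100,240,250,196.67,4.92
78,5,5,10,3130,1048.33,209.67
79,30,1.2,625,500,375.40,12.51
80,250,20,100,500,206.67,1.21
81,2,30,60,60,50.00,25.00
82,250,10,100,240,116.67,2.14
83,30,10,10,250,90.00,3.00
84,20,100,100,750,316.67,15.83
85,6,62.5,3130,70,1087.50,181.25
86,60,781,200,350,443.67,7.39
87,6,625,625,15,421.67,70.28
88,30,30,60,60,50.00,1.67
89,100,625,625,15,421.67,4.22
90,100,150,30,200,126.67,1.27
91,781,60,200,30,96.67,2.69
92,625,625,625,350,533.33,1.17
93,15,100,625,6,243.67,16.24
94,625,625,625,350,533.33,1.17
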