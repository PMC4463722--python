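entry,query_loel,analog1_loel,analog2_loel,analog3_loel,printed_pred,printed_fold
1,30,30,30,20,26.67,1.13
2,30,30,1000,6,345.33,11.51
3,1.5,200,5,0.75,68.58,45.72
4,1250,750,1000,100,616.67,2.03
5,50,781,60,250,363.67,7.27
6,0.1,30,10,10,16.67,166.67
7,1000,1000,1000,11,670.33,1.49
8,20,150,200,6,118.67,5.93
9,20,5,10,5,6.67,3.00
10,100,250,100,500,283.33,2.83
11,110,1000,1000,11,670.33,6.09
12,1000,1000,100,750,616.67,1.62
13,33,30,10,10,16.67,1.98
14,30,3130,2500,200,1943.33,64.78
15,10,781,60,30,290.33,29.03
16,300,100,300,40,146.67,2.05
17,2,30,30,10,23.33,11.67
18,200,350,1000,1000,783.33,3.92
19,125,10,250,40,100.00,1.25
20,50,1000,100,30,376.67,7.53
21,100,350,625,6,327.00,3.27
22,10,6,15,10,10.33,1.03
23,150,1000,750,200,650.00,4.33
24,4,6,625,625,418.67,104.67
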