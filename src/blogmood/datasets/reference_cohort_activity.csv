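participant_id,phq9_completed,gad7_completed,total_posts,total_words,mean_words_per_post
1,9,9,6,2695,449.17
2,1,1,23,11004,478.43
3,3,3,4,2227,556.75
4,9,9,32,1822,56.94
5,1,1,4,1009,252.25
6,1,1,2,376,188.00
7,7,7,91,26947,296.12
8,3,3,5,922,184.40
9,9,9,13,2612,200.92
10,9,7,47,6773,144.11
11,9,9,4,506,126.50
12,17,17,8,3875,484.38
13,9,9,34,7686,226.06
14,9,9,21,3041,144.81
15,18,18,35,3909,111.69
16,1,1,1,217,217.00
17,9,9,1,6,6.00
18,10,10,5,1426,285.20
19,9,9,4,597,149.25
20,5,5,11,1102,100.18
21,6,6,39,4981,127.72
22,1,1,1,316,316.00
23,9,8,6,555,92.50
24,18,18,34,5585,164.26
25,6,1,6,1417,236.17
26,18,18,55,11804,214.62
27,18,18,128,15718,122.80
28,1,1,2,1564,782.00
29,17,14,3,58,19.33
30,8,8,3,318,106.00
31,4,4,115,3729,32.43
32,9,9,37,9481,256.24
33,1,1,18,1100,61.11
34,1,1,1,18,18.00
35,9,9,54,1564,28.96
36,2,2,61,1266,20.75
37,9,9,329,8545,25.97
38,2,2,8,335,41.88
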