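s,eta,stderr
1,0.7419,0.4058
2,0.1524,0.8593
3,1.757,0.966
4,4.968,0.9863
5,3.6684,1.0013
6,2.6104,1.0366
7,2.2959,1.1737
8,2.5219,1.1472
9,2.1194,1.1662
10,1.9798,1.3632
11,1.7527,1.2426
12,1.8581,1.3925
13,1.3547,1.3502
14,1.1259,1.3664
15,1.1307,1.3738
16,0.7016,1.2889
17,0.311,1.4632
18,0.0,1.3499
19,1.1614,1.609
20,2.053,1.2829
21,2.6421,1.4534
22,2.6372,1.5238
23,3.8278,1.3504
24,4.4228,1.3073
25,4.8231,1.1357
26,5.5141,1.325
27,6.2741,1.3411
28,6.9414,1.1612
29,7.6615,1.1643
30,7.7127,1.2327
31,7.773,1.1631
32,7.3815,0.9879
33,6.6497,1.024
34,5.9324,0.8014
35,5.9647,0.9544
36,6.0308,1.0334
37,6.4437,1.0182
38,6.8078,0.9197
39,7.2032,0.7735
40,7.1695,0.7736
41,7.141,0.8703
42,7.0147,0.797
43,6.7631,0.6877
44,6.4834,0.7316
45,6.3448,0.5528
46,6.2557,0.5809
47,6.1832,0.5531
48,6.1861,0.5168
49,6.2418,0.5805
50,6.1068,0.5198
51,6.0594,0.4678
52,6.1272,0.399
53,6.3717,0.4168
54,6.2851,0.4389
55,6.3598,0.3907
56,6.4407,0.3316
57,6.4528,0.3245
58,6.3587,0.3117
59,6.4677,0.3101
60,6.549,0.2639
61,6.5864,0.2476
62,6.5501,0.2615
63,6.7334,0.2877
64,6.6167,0.2619
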