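# SSDE conversion factors, 32-cm body CTDI phantom reference.
# Tabulated at 1-cm steps from the published exponential form
# f(D_w) = 3.704369 * exp(-0.03671937 * D_w) (AAPM size-specific
# dose estimate tables for the body phantom; agreement with the
# printed table is better than 1%).
diameter_cm,factor
6,2.9719
7,2.8647
8,2.7615
9,2.6619
10,2.5659
11,2.4734
12,2.3842
13,2.2983
14,2.2154
15,2.1355
16,2.0586
17,1.9843
18,1.9128
19,1.8438
20,1.7774
21,1.7133
22,1.6515
23,1.5920
24,1.5346
25,1.4792
26,1.4259
27,1.3745
28,1.3249
29,1.2772
30,1.2311
31,1.1867
32,1.1440
33,1.1027
34,1.0630
35,1.0246
36,0.9877
37,0.9521
38,0.9178
39,0.8847
40,0.8528
41,0.8220
42,0.7924
43,0.7638
44,0.7363
45,0.7097
46,0.6842
47,0.6595
48,0.6357
49,0.6128
50,0.5907
51,0.5694
52,0.5489
53,0.5291
54,0.5100
55,0.4916
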