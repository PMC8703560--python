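hour,price_cents_per_kwh
0,8.2
1,8.0
2,7.9
3,7.9
4,8.1
5,8.6
6,10.5
7,13.0
8,15.2
9,16.0
10,16.8
11,17.5
12,18.0
13,18.2
14,17.8
15,16.9
16,16.5
17,17.6
18,19.4
19,20.1
20,18.3
21,14.6
22,11.2
23,9.0
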