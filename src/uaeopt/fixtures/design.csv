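sample_id,time,temperature,ratio
1,10,25,10
2,10,50,15
3,10,75,20
4,20,25,15
5,20,50,10
6,20,50,20
7,20,75,15
8,30,25,20
9,30,50,10
10,30,50,15
11,30,75,10
12,10,25,20
13,20,25,10
14,10,75,15
15,30,75,20
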