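event_no	emotion	emotion_no	onset	offset
1	nostalgic	3	0	36
2	anxious	4	45	93
3	sad	4	102	150
4	happy	5	160	208
5	calm	5	219	270
6	anxious	5	279	327
7	sad	5	336	384
8	calm	6	393	459
9	happy	6	468	495
10	sad	6	504	558
11	anxious	6	567	615
12	happy	7	627	675
13	calm	7	684	728
14	sad	7	735	807
15	anxious	7	816	846
16	nostalgic	4	852	894
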