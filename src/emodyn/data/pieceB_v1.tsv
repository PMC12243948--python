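event_no	emotion	emotion_no	onset	offset
1	nostalgic	3	0	36
2	sad	4	45	93
3	anxious	4	102	150
4	calm	5	159	210
5	happy	5	219	267
6	anxious	5	279	327
7	sad	5	336	390
8	happy	6	399	426
9	calm	6	435	501
10	sad	6	510	558
11	anxious	6	567	615
12	calm	7	625	672
13	happy	7	678	726
14	anxious	7	735	765
15	sad	7	771	843
16	nostalgic	4	852	894
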