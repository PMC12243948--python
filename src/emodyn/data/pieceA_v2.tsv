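event_no	emotion	emotion_no	onset	offset
1	nostalgic	1	0	60
2	happy	1	69	120
3	calm	1	129	181
4	sad	1	194	230
5	anxious	1	234	291
6	happy	2	300	348
7	calm	2	357	393
8	anxious	2	402	441
9	sad	2	447	495
10	calm	3	506	546
11	happy	3	555	609
12	anxious	3	615	663
13	sad	3	672	720
14	calm	4	729	780
15	happy	4	789	827
16	nostalgic	2	834	894
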