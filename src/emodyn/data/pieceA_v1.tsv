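event_no	emotion	emotion_no	onset	offset
1	nostalgic	1	0	60
2	calm	1	69	121
3	happy	1	132	183
4	sad	1	192	240
5	anxious	1	249	297
6	happy	2	306	360
7	calm	2	368	408
8	anxious	2	417	474
9	sad	2	485	521
10	calm	3	525	561
11	happy	3	570	618
12	sad	3	627	675
13	anxious	3	684	723
14	happy	4	730	768
15	calm	4	774	825
16	nostalgic	2	834	894
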