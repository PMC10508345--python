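chrom	arm	start	end
1	p	0	125000000
1	q	128000000	252000000
2	p	0	93000000
2	q	96000000	246000000
3	p	0	91000000
3	q	94000000	201000000
4	p	0	50000000
4	q	53000000	194000000
5	p	0	48000000
5	q	51000000	184000000
6	p	0	61000000
6	q	64000000	174000000
7	p	0	60000000
7	q	63000000	162000000
8	p	0	45000000
8	q	48000000	149000000
9	p	0	49000000
9	q	52000000	144000000
10	p	0	40000000
10	q	43000000	138000000
11	p	0	53000000
11	q	56000000	138000000
12	p	0	36000000
12	q	39000000	137000000
13	p	0	17000000
13	q	20000000	118000000
14	p	0	17000000
14	q	20000000	110000000
15	p	0	19000000
15	q	22000000	106000000
16	p	0	36000000
16	q	39000000	93000000
17	p	0	24000000
17	q	27000000	84000000
18	p	0	17000000
18	q	20000000	81000000
19	p	0	26000000
19	q	29000000	62000000
20	p	0	28000000
20	q	31000000	66000000
21	p	0	13000000
21	q	16000000	51000000
22	p	0	15000000
22	q	18000000	54000000
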