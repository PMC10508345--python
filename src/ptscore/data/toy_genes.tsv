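gene	chrom	pos
TP53	17	7000000
YWHAE	17	1000000
BRCA1	17	47000000
CDK12	17	37000000
RAD51D	17	33000000
RAD51C	17	56000000
BRCA2	13	32000000
FANCE	6	35000000
ATM	11	90000000
CHEK2	22	25000000
FAN1	15	30000000
FAT3	11	70000000
RYR2	1	200000000
MAP2	2	180000000
ASCC3	6	100000000
CDH11	16	65000000
DNAH10	12	120000000
DYNC1H1	14	95000000
ERCC6	10	60000000
PTEN	10	89000000
RIF1	2	150000000
POLD2	7	50000000
PRKDC	8	50000000
SMARCA4	19	11000000
TDG	12	104000000
TTK	6	80000000
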