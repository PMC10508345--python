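channel	ID1	ID2	ID6	ID8
1:Del:C:0	0.0	0.0	0.0	0.0
1:Del:C:1	0.1841828655	0.0	0.0108869999	0.0837984408
1:Del:C:2	0.0	2e-07	0.0	0.1221943712
1:Del:C:3	7e-08	0.0986274639	0.0262271697	0.0
1:Del:C:4	0.0	0.0729391429	0.0077427399	0.0
1:Del:C:5	0.00048319	0.0133090805	0.0463100995	3.55e-05
1:Del:T:0	0.0	1.304e-05	0.0	0.0
1:Del:T:1	0.0	8.98e-06	0.00070506	0.0
1:Del:T:2	2.81e-06	0.025516871	0.0156455798	0.0083409101
1:Del:T:3	0.0	1e-08	0.0520468195	0.0
1:Del:T:4	0.00012757	0.049098932	0.0108304499	0.00060674
1:Del:T:5	0.0	1.348e-05	0.0	3.5e-07
1:Ins:C:0	0.0	0.0	6.651e-05	0.0
1:Ins:C:1	0.0109914703	0.0	0.0261906697	0.1388351314
1:Ins:C:2	0.2567637577	9e-08	0.00134455	0.0282762703
1:Ins:C:3	0.0355605311	0.0	0.0	0.0
1:Ins:C:4	3.63e-06	1e-08	0.0269044997	0.0
1:Ins:C:5	9.49e-06	0.126048185	0.0297043697	0.0
1:Ins:T:0	0.0	0.00036596	0.0	1.503e-05
1:Ins:T:1	1.04e-05	0.0	2e-08	0.0
1:Ins:T:2	1.9e-07	2.5e-07	0.0066782299	0.0
1:Ins:T:3	0.0	0.0	0.0	0.0
1:Ins:T:4	0.0465120414	0.0	0.0	0.00090628
1:Ins:T:5	0.0687703821	0.0	0.0	0.00031242
2:Del:R:0	1.079e-05	0.073916713	2.698e-05	0.0463489505
2:Del:R:1	0.0	9.9e-07	0.0	0.00051059
2:Del:R:2	0.0	0.0	0.0518518895	8.448e-05
2:Del:R:3	0.0	0.1195444648	0.0	0.00318869
2:Del:R:4	1e-08	7.3e-07	0.00018576	0.0122578701
2:Del:R:5	0.0478516014	0.0	0.00405388	3.97e-05
3:Del:R:0	0.0	1.35e-06	0.0	0.0006618
3:Del:R:1	0.0197229106	0.0	0.0	0.00070931
3:Del:R:2	0.0	1e-08	0.0468098995	0.0
3:Del:R:3	0.00114148	2e-08	0.0367456596	0.00069927
3:Del:R:4	1.1e-07	0.1628778165	0.00218121	0.0
3:Del:R:5	0.0215844906	0.0	0.0360325996	0.00036741
4:Del:R:0	0.00019816	0.00036565	1.501e-05	1e-08
4:Del:R:1	0.0	5.3e-07	0.0397954396	0.0154634602
4:Del:R:2	0.0	0.0	0.00015545	0.00470605
4:Del:R:3	0.0	0.0	0.0	0.0
4:Del:R:4	0.0	0.0	0.0	0.0
4:Del:R:5	2e-08	0.0	1e-08	0.0
5:Del:R:0	1e-08	0.0	0.0	0.0
5:Del:R:1	0.0439888213	2.22e-06	0.0744825893	0.0
5:Del:R:2	1.402e-05	0.0	0.0	0.0210555102
5:Del:R:3	5.538e-05	0.0300865412	8.3e-07	0.0
5:Del:R:4	1.87e-06	0.0	0.0406385196	0.0
5:Del:R:5	0.0	0.0024223301	0.0	0.0547391305
2:Ins:R:0	0.0	0.0	0.00061168	1.01e-06
2:Ins:R:1	0.0	0.0	0.0	0.0
2:Ins:R:2	0.0033543801	0.0	0.0	4.921e-05
2:Ins:R:3	3.144e-05	7.101e-05	0.0727063993	3.827e-05
2:Ins:R:4	0.0	0.026028661	0.0	0.0
2:Ins:R:5	0.0	0.0	0.0	0.0
3:Ins:R:0	0.0	0.0	0.00016808	0.0
3:Ins:R:1	9.354e-05	0.0	0.0121113599	0.0
3:Ins:R:2	0.0	2e-08	0.00014727	0.0
3:Ins:R:3	0.0	0.0013911901	0.0065811799	1e-08
3:Ins:R:4	0.0045079401	0.0	0.00391823	0.0
3:Ins:R:5	2.61e-06	0.0076422103	0.00012763	5.6e-07
4:Ins:R:0	0.00097339	0.00064402	0.1299685687	0.0013065
4:Ins:R:1	0.0	0.0182492907	0.0262669797	5.81e-05
4:Ins:R:2	2.6e-06	0.0	0.0198466298	0.00011626
4:Ins:R:3	6.74e-06	0.0	0.0	0.00060015
4:Ins:R:4	0.0	0.0	0.0	0.0
4:Ins:R:5	0.0	0.0182366407	0.0190046498	0.00010294
5:Ins:R:0	0.0	0.0	0.0145309699	5.48e-05
5:Ins:R:1	0.1363108341	0.0	0.0	0.0
5:Ins:R:2	0.0065173702	0.0	2.44e-06	2e-08
5:Ins:R:3	2e-08	4.53e-06	0.0	8.03e-06
5:Ins:R:4	0.0	0.0	0.00038634	0.0471536905
5:Ins:R:5	3.243e-05	0.00021498	0.0052557799	0.0240546402
2:Del:M:1	0.0479142314	0.0795210132	0.0058112199	0.0
3:Del:M:1	0.0	0.0	0.0402393296	0.0
3:Del:M:2	1e-07	0.025015041	1e-08	0.0612015306
4:Del:M:1	0.00047557	1.09e-06	0.0230308598	0.0
4:Del:M:2	0.0	1e-08	0.0249099598	0.0833471208
4:Del:M:3	0.00018619	0.0	2.565e-05	0.1526939815
5:Del:M:1	0.0	0.00016898	0.0	0.0
5:Del:M:2	0.0431855013	0.00040771	5.078e-05	0.0429196104
5:Del:M:3	3.142e-05	0.0283648811	3.851e-05	0.0
5:Del:M:4	0.0	6.66e-06	0.0	2e-08
5:Del:M:5	0.0183856206	0.0188710008	0.0	0.0421398704
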