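channel	SBS1	SBS3	SBS5	SBS39
A[C>A]A	0.0	0.0138024097	2.6e-07	0.00034492
A[C>A]C	1.18e-06	0.0114794198	0.00029559	3.8e-07
A[C>A]G	0.0037068701	0.0295496794	3.03e-06	3.41e-06
A[C>A]T	0.0369203211	0.0030779499	0.0138520107	3e-08
C[C>A]A	0.0	0.0053645099	7.56e-05	3.1e-06
C[C>A]C	0.00069889	0.0213157196	6.109e-05	0.00040395
C[C>A]G	0.0	0.0166076797	0.0	0.0
C[C>A]T	0.00016816	0.0193968996	0.0	0.0
G[C>A]A	0.0688706521	0.0061789199	0.0	2.19e-06
G[C>A]C	0.0	1.72e-06	0.0	0.0
G[C>A]G	3.55e-05	0.0266198095	0.0237889212	0.0
G[C>A]T	2.264e-05	1.658e-05	3e-08	2.049e-05
T[C>A]A	0.0	0.0	0.0116732506	1.092e-05
T[C>A]C	7e-08	0.0025627599	0.0007702	1.71e-06
T[C>A]G	0.0231445207	0.0083926798	0.00061558	0.0
T[C>A]T	0.0	0.00174817	3.1e-07	0.05119047
A[C>G]A	0.0	0.0129519797	0.0076816404	0.0
A[C>G]C	0.0125559604	3e-08	3e-08	2.66e-06
A[C>G]G	0.0	0.0	0.0143588607	0.00016324
A[C>G]T	0.1043236131	0.0228002995	0.0359716318	0.0
C[C>G]A	1.24e-06	0.00184143	0.0272544514	0.0006567
C[C>G]C	0.00015129	0.0132451997	0.0340798417	0.0
C[C>G]G	8.4e-07	0.0252479695	0.0	0.0
C[C>G]T	5.283e-05	0.0263012495	0.0	0.00012771
G[C>G]A	0.0	1.011e-05	0.0381485119	1e-08
G[C>G]C	0.0	0.0	1e-08	0.00803194
G[C>G]G	0.0	0.0	0.00087002	0.0
G[C>G]T	6.4e-07	9.385e-05	0.00021392	8.466e-05
T[C>G]A	5e-08	0.0247186395	0.0	1e-08
T[C>G]C	0.0	0.0067677299	0.0124865706	0.0
T[C>G]G	4e-08	0.0224129296	0.0	0.0012898
T[C>G]T	0.0007108	0.0	0.0262747513	1.37e-06
A[C>T]A	4.1e-07	0.0051343899	0.0215725911	0.0
A[C>T]C	0.0062059102	0.00011779	0.00076756	3e-08
A[C>T]G	0.00128319	0.0	0.0	0.0
A[C>T]T	6.69e-06	0.0171393497	0.0293823515	2.3e-07
C[C>T]A	0.0	0.0272373095	0.0	0.00736311
C[C>T]C	0.0	0.0	0.0161867108	0.0
C[C>T]G	0.2104819163	0.0	0.00062266	0.0
C[C>T]T	0.0	4.35e-06	0.0426094221	0.0
G[C>T]A	0.0	0.0164583097	0.0059608003	0.0
G[C>T]C	0.0065006902	0.0030235299	5.9e-07	0.00014178
G[C>T]G	0.00027577	0.0199986496	0.0	0.0
G[C>T]T	6.01e-06	1.49e-06	0.0098271205	1.88e-06
T[C>T]A	0.0	0.00117506	0.0153132008	0.10332864
T[C>T]C	0.0	0.0085720798	1.316e-05	0.00351465
T[C>T]G	0.0135591804	0.00237231	0.0	0.0056592
T[C>T]T	0.0	3.17e-06	5.21e-06	0.0
A[T>A]A	0.0167600505	0.0	2.221e-05	0.10838041
A[T>A]C	0.0	0.0207225096	0.0727944936	0.01409872
A[T>A]G	0.0	0.0211490896	0.0446092222	0.00336794
A[T>A]T	0.0894237127	0.00074355	0.0082941104	0.05402624
C[T>A]A	0.0454303214	0.0145009597	0.0177375709	0.00014773
C[T>A]C	0.0	0.0180517396	0.0165091808	5.4e-07
C[T>A]G	0.0	0.0	0.0258827413	0.0
C[T>A]T	0.0045591701	0.0162540197	0.0132093507	0.0
G[T>A]A	1e-08	0.0049026499	0.0	0.0
G[T>A]C	0.0	0.0124727898	0.0	0.0
G[T>A]G	0.0	0.0335072693	0.0	0.0
G[T>A]T	0.0	5e-08	0.0381481419	0.06260559
T[T>A]A	0.0	0.0185729796	0.0144400007	0.00967504
T[T>A]C	0.0	0.0061085799	0.0362562018	0.0
T[T>A]G	0.0	0.0092424098	1e-08	0.16261538
T[T>A]T	1.635e-05	2e-07	1.01e-06	3.96e-06
A[T>C]A	0.0	0.0	0.00042149	0.0
A[T>C]C	0.0	7e-08	0.0	0.0
A[T>C]G	0.0144347504	1e-08	0.0095410705	0.0
A[T>C]T	0.1238906137	0.0	0.020917051	0.0
C[T>C]A	0.0	0.0157698397	0.020306471	6.853e-05
C[T>C]C	0.0966052429	0.0084545198	0.0074635204	2.156e-05
C[T>C]G	0.033902381	0.0229527595	0.0010343801	1e-08
C[T>C]T	1e-08	0.00034966	0.0050034903	0.01541615
G[T>C]A	0.0	0.0104032898	0.0302747215	0.01257334
G[T>C]C	0.0	0.0300164694	0.0114541406	0.0
G[T>C]G	2.281e-05	0.0181133896	0.0098055905	0.0
G[T>C]T	1.6e-07	0.0276982194	0.0158891508	6e-08
T[T>C]A	0.0	0.0123765898	0.00074437	5.9e-07
T[T>C]C	0.0	0.0297459194	0.0104344905	0.0
T[T>C]G	0.0150856405	0.00051556	0.0126357706	7.1e-05
T[T>C]T	0.0	0.0712141986	1e-08	0.00963721
A[T>G]A	0.0	0.00215637	0.0	0.0
A[T>G]C	0.00117898	0.0242259095	0.0073696004	0.15248011
A[T>G]G	1e-08	0.0105465198	0.0168670008	4.02e-06
A[T>G]T	1.33e-06	0.00234399	0.0	5e-08
C[T>G]A	0.0	0.0042169299	0.0115601606	0.00012072
C[T>G]C	0.0	6.1e-07	0.0177160509	0.10021999
C[T>G]G	8e-08	0.0076943698	0.0	0.0
C[T>G]T	1.01e-06	0.0297717694	0.0	0.02729305
G[T>G]A	0.0040097901	0.0075400698	0.0530029627	0.00012863
G[T>G]C	3.37e-06	0.0270902195	0.0	0.01388878
G[T>G]G	0.0231169007	0.0	0.0251329013	3e-08
G[T>G]T	0.0288092709	0.0142950697	0.0103615305	0.06751698
T[T>G]A	6.26e-06	4.312e-05	7.865e-05	0.0
T[T>G]C	0.0130559004	0.0044959599	2.9e-07	0.00328845
T[T>G]G	0.0	0.0086759698	1.26e-05	0.0
T[T>G]T	0.0	0.0093197198	0.0233308012	0.0
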