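signature_group	feature_id	tentative_identification	metabolite_class	group1	group2	group3	group4	group5
group1	1.93_481.0621	HHDP-glucose	Ellagitannins	667.5	18.8	107.9	28.5	51.4
group1	2.06_167.0549	Ribonic acid	Sugar acids and derivatives	1131.7	30.8	71.5	23.2	44.7
group1	2.89_344.0743	Theogallin	Phenolic acids	31146.8	14975.9	12871.7	8404.9	12089.9
group1	3.83_306.0740	Gallocatechin	Flavanols	16166.9	7079.3	6195.0	5533.4	6741.1
group1	4.80_593.1297	EC-GC dimer isomer 4	Proanthocyanidins	1176.5	491.2	377.7	360.7	454.4
group1	4.93_593.1293	EC-GC dimer isomer 5	Proanthocyanidins	1600.1	566.2	396.9	323.0	412.8
group1	5.11_577.1348	Procyanidin B3	Proanthocyanidins	1201.0	307.4	235.4	351.5	341.6
group1	5.34_290.0791	Catechin	Flavanols	24258.8	4032.7	3625.6	3542.0	3670.3
group1	5.36_183.0298	Methylgallate	Phenolic acids	4633.4	1208.2	1888.1	1306.2	1000.6
group1	5.51_354.0948	Chlorogenic acid	Phenolic acids	6272.5	803.9	265.5	265.9	134.6
group1	5.83_747.1552	EC-EGCG dimer	Proanthocyanidins	3602.3	907.5	512.1	517.6	588.6
group1	6.25_290.0794	Epicatechin	Flavanols	116557.4	48408.2	57998.7	57396.7	52306.4
group1	6.57_551.1402	Gentioside	Xanthone glycosides	735.6	137.8	248.7	171.1	242.1
group1	6.63_318.0476	Trigalloylglucose isomer 2	Hydrolysable tannins	9744.1	3327.0	3954.0	1512.2	1156.8
group1	7.69_609.1438	Rutin	Flavonol glycosides	11904.4	1726.1	2665.6	1859.8	1404.2
group1	6.78_729.1455	Galloylprocyanidin dimer isomer 1	Proanthocyanidins	8493.2	1435.0	1174.9	1070.7	1255.0
group1	7.85_442.0901	Epicatechin 3-O-gallate	Flavanols	334280.4	151298.2	137580.1	121634.2	137860.9
group1	7.88_303.0485	Tricetin	Flavones	4889.7	818.6	1984.6	2437.5	1774.5
group1	8.00_464.0948	Quercetin 3-O-glucoside	Flavonol glycosides	7216.1	1158.4	2866.5	1918.1	1710.0
group1	8.26_739.2086	Kaempferol 3-neohesperidoside-7-rhamnoside	Flavonol glycosides	1035.9	1.2	356.9	20.5	0.4
group1	8.42_594.1530	Kaempferol 3-O-rutinoside	Flavonol glycosides	3885.6	1526.3	874.5	431.7	497.0
group1	9.37_441.0818	Digalloylprocyanidin dimer	Proanthocyanidins	504.5	116.2	117.1	85.6	93.7
group1	10.24_451.1235	Sarmenoside II	Flavonol glycosides	1481.6	0.0	22.2	0.5	98.1
group1	10.55_443.1260	Kaempferol 3-(4''-(E)-p-coumaroylrobinobioside)-7-rhamnoside isomer 1	Flavonol glycosides	612.2	5.4	6.0	0.4	93.6
group1	11.20_448.2300	Linalool primeveroside isomer 1	Terpenoid glycosides	1807.1	549.0	765.8	559.3	691.2
group2	5.01_242.0423	Digalloylglucose isomer 1	Hydrolysable tannins	2155.5	9033.6	718.2	368.6	218.5
group2	10.48_517.1448	Camellikaempferoside C isomer 1	Flavonol glycosides	113.8	4182.1	449.6	327.3	1193.9
group2	10.74_517.1448	Camellikaempferoside C isomer 2	Flavonol glycosides	5.7	1459.3	116.9	90.2	358.9
group2	10.90_436.1180	Camellikaempferoside A isomer 1	Flavonol glycosides	113.9	1616.3	59.5	45.3	54.1
group2	11.13_871.2298	Camellikaempferoside A isomer 2	Flavonol glycosides	23.0	518.4	7.8	5.0	8.3
group2	11.33_1189.5616	Theasaponin A1	Triterpenoid saponins	10.9	623.5	73.6	52.3	193.7
group2	16.41_1189.5400	C60H86O24	Unknown	14.9	677.3	72.4	21.0	237.3
group2	16.80_1131.5352	Tragopogonsaponin E	Triterpenoid saponins	122.9	1685.5	375.2	34.5	350.9
group2	16.89_731.4146	C44H58O9	Unknown	74.1	1173.1	431.9	347.6	461.7
group4	16.36_1157.5720	Eupteleasaponin IV isomer 2	Triterpenoid saponins	0.0	1.6	52.9	940.7	19.7
group5	7.42_472.1004	EGCG3''Me	Flavanols	577.4	436.9	199.8	3086.1	8095.4
group5	8.89_456.1053	ECG3''Me	Flavanols	227.9	187.4	46.2	784.1	1666.9
group5	13.40_451.1377	C25H22O8	Unknown	65.0	158.5	307.6	376.0	821.8
group5	13.40_467.1343	C25H24O9	Unknown	7.2	144.3	360.7	464.8	1051.2
group5	16.41_1125.5460	Xanifolia-Y3 isomer 1	Triterpenoid saponins	13.3	127.7	152.8	7.4	617.5
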