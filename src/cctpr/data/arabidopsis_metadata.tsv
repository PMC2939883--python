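locus_id	name	lengths	additional_domains	novel	n_tpr_domains	mrna_species
AT4G30480	AtTPR1	161/208/277		true	one	3
AT1G04130	AtTPR2	360		true	one	1
AT1G04190	AtTPR3	328		true	one	1
AT1G04530	AtTPR4	310		true	one	1
AT1G56440	AtTPR5	476		true	one	1
AT1G58450	AtTPR6	164		true	one	1
AT5G21990	AtTPR7	554		true	one	1
AT4G08320	AtTPR8	426/427		true	one	2
AT1G33400	AtTPR9	798	SET	true	one	1
AT3G04710	AtTPR10	455/456	Ankyrin	true	one	2
AT2G25290	AtPhox1	697	Phox/PB1	true	one	1
AT1G62390	AtPhox2	751	Phox/PB1	true	one	1
AT5G20360	AtPhox3	809	Phox/PB1	true	one	1
AT4G32070	AtPhox4	811	Phox/PB1	true	one	1
AT4G22670	AtTPR11	441	Heat shock chaperonin-binding	true	one	1
AT2G15790	AtSquint	361	Cyclophilin	false	one	1
AT3G54010	AtPAS1	635/545	Peptidyl-prolyl-cis-trans isomerase	false	one	2
AT3G25230	AtROF1	551/562	Peptidyl-prolyl-cis-trans isomerase	false	one	2
AT5G48570	AtROF2	578	Peptidyl-prolyl-cis-trans isomerase	false	one	1
AT3G21640	AtTWD1	365	Peptidyl-prolyl-cis-trans isomerase	false	one	1
AT3G07370	AtCHIP	278	U-box	false	one	1
AT2G42810	AtPP5	484/538	PP5	false	one	2
AT3G17970	AtToc64-III	589	Amidase	false	one	1
AT5G09420	AtToc64-V	603	Amidase	false	one	1
AT1G78120	AtTPR12	530		true	more_than_one	1
AT5G10090	AtTPR13	594		true	more_than_one	1
AT5G65160	AtTPR14	593		true	more_than_one	1
AT2G41520	AtTPR15	1077/1108	DnaJ	true	more_than_one	2
AT5G12430	AtTPR16	1165	DnaJ	true	more_than_one	1
AT1G53300	AtTTL1	699	Thioredoxin	true	more_than_one	1
AT3G14950	AtTTL2	721	Thioredoxin	true	more_than_one	1
AT2G42580	AtTTL3	691	Thioredoxin	true	more_than_one	1
AT3G58620	AtTTL4	682	Thioredoxin	true	more_than_one	1
AT1G12270	AtHop1	572	Heat shock chaperonin-binding	false	more_than_one	1
AT1G62740	AtHop2	571	Heat shock chaperonin-binding	false	more_than_one	1
AT4G12400	AtHop3	530/558	Heat shock chaperonin-binding	false	more_than_one	2
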