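group	family	taxon	dna_k	dna_n	pollen_k	pollen_n	pollen_min	pollen_mean	pollen_max	macro
tree/shrub	Podocarpaceae	Dacrydium cupressinum			29	35	0	0.5	2.5
tree/shrub	Podocarpaceae	Prumnopitys ferruginea			18	35	0	0.3	1.5
tree/shrub	Podocarpaceae	Prumnopitys taxifolia			26	35	0	0.6	2.6
tree/shrub	Podocarpaceae	Podocarpus			17	35	0	0.2	1.2
tree/shrub	Podocarpaceae	Halocarpus			2	35	0	0.02	0.3
tree/shrub	Podocarpaceae	Phyllocladus			15	35	0	0.3	1.8
tree/shrub	Fagaceae	Nothofagus menziesii	5	8	30	35	0	1.3	3.6	L:6
tree/shrub	Fagaceae	Fuscospora			35	35	0.3	4.8	15.2
tree/shrub	Myrtaceae	Metrosideros			4	35	0	0.04	0.4
tree/shrub	Myrtaceae	Neomyrtus			6	35	0	0.1	0.9
tree/shrub	Araliaceae	Pseudopanax	1	8	4	35	0	0.1	1.4
tree/shrub	Araliaceae	Pseudopanax colensoi			8	35	0	0.6	16.9
tree/shrub	Onagraceae	Fuchsia excorticata	1	8	9	35	0	0.3	3.8	S:2
tree/shrub	Chloranthaceae	Ascarina lucida			2	35	0	0.01	0.3
tree/shrub	Paracryphiaceae	Quintinia	1	8
tree/shrub	Elaeocarpaceae	Aristotelia			1	35	0	0.01	0.3
tree/shrub	Elaeocarpaceae	Elaeocarpus/Aristotelia	7	8
tree/shrub	Grisiliniaceae	Griselinia	4	8	1	35	0	0.01	0.4
tree/shrub	Cunoniaceae	Weinmannia	2	8
tree/shrub	Piperaceae	Macropiper	1	8
tree/shrub	Myrsinaceae	Myrsine	2	8	5	35	0	0.1	0.9
tree/shrub	Rubiaceae	Coprosma			18	35	0	0.9	8.6
tree/shrub	Rubiaceae	Coprosma cf. arborea	1	8
tree/shrub	Rubiaceae	Rubiaceae (Undetermined)	3	8
tree/shrub	Plantaginaceae	Parahebe			1	35	0	0.01	0.4
tree/shrub	Plantaginaceae	Veronica	1	8
tree/shrub	Ericaceae	Ericaceae (Undetermined)	1	8	10	35	0	0.4	6.8
tree/shrub	Ericaceae	Gaultheria	1	8						S:10
tree/shrub	Ericaceae	Dracophyllum	1	8
tree/shrub	Epacridaceae	Epacridaceae (Undetermined)								L:1
liane	Rosaceae	Rubus			1	35	0	0.01	0.3
liane	Polygonaceae	Muehlenbeckia			1	35	0	0.02	0.7
dicot herb	Asteraceae	Asteraceae (Undetermined)	1	8	33	35	0	5.9	32.5
dicot herb	Asteraceae	Lactuceae			18	35	0	0.9	6.5
dicot herb	Rosaceae	Acaena	2	8	19	35	0	1.5	17.3
dicot herb	Thymeleaceae	Pimelea			1	35	0	0.01	0.3
dicot herb	Thymeleaceae	Kelleria			1	35	0	0.01	0.3
dicot herb	Brassicaceae	Brassicaceae (Undetermined)	1	8	26	35	0	1.5	7.5
dicot herb	Lobeliaceae	cf. Pratia								S:4
dicot herb	Onagraceae	Epilobium			14	35	0	0.1	1.0
dicot herb	Gentianaceae	Gentiana			25	35	0	3.2	14.6
dicot herb	Gentianaceae	Gentianaceae (Undetermined)	1	8
dicot herb	Droseraceae	Drosera			5	35	0	0.1	1.4
dicot herb	Plantaginaceae	Plantago			18	35	0	0.6	2.8
dicot herb	Caryophyllaceae	Colobanthus								S:2
dicot herb	Caryophyllaceae	Caryophyllaceae (Undetermined)			16	35	0	0.1	0.4
dicot herb	Oxalidaceae	Oxalis	2	8
dicot herb	Boraginaceae	Myosotis	2	8	32	35	0	1.6	7.7
dicot herb	Halagoraceae	Myriophyllum			1	35	0	0.01	0.3
dicot herb	Donatiaceae	Donatia			2	35	0	0.02	0.3
dicot herb	cf. Urticaceae	cf. Urtica								S:5
dicot herb	Ranunculaceae	Ranunculus	1	8	24	35	0	0.9	4.9	S:10
dicot herb	Stylidiaceae	Forstera/Phyllachne	1	8
dicot herb	Loganiaceae	Mitrasacme	1	8
dicot herb	Apiaceae	Apiaceae (Undetermined)			20	35	0	4.2	27.4
dicot herb	Apiaceae	Anisotome			3	35	0	0.2	6.1
dicot herb	Violaceae	Viola	1	8
monocot	Poaceae	Poaceae (Undetermined)	1	8	35	35	0.7	36.4	86.0	S:1,Fl:3
monocot	Cyperaceae	Cyperaceae (Undetermined)	2	8	27	35	0	5.7	64.7
monocot	Cyperaceae	cf. Carex								S:3
monocot	Cyperaceae	cf. Scirpus								S:13
monocot	Asteliaceae	Astelia			20	35	0	7.2	84.1
monocot	Xanthorrhoeaceae	Bulbinella			9	35	0	0.1	1.7
monocot	Xanthorrhoeaceae	Phormium			14	35	0	2.9	76.7
fern	Unidentified	Unidentified fern								L:3
fern	Unidentified	Monolete fern			34	35	0	7.3	32.3
fern	Cyatheaceae	Cyathea colensoi			26	35	0	4.0	38.6
fern	Hymenophyllaceae	Hymenophyllum			9	35	0	0.3	3.9
fern	Ophioglossaceae	Ophioglossum			15	35	0	0.5	3.8
fern	Lycopodiaceae	Lycopodium australianum			2	35	0	0.1	1.8
fern	Lycopodiaceae	Lycopodium scariosum			2	35	0	0.1	2.9
fern	Anthocerotaceae	Anthoceros			1	35	0	0.01	0.3
bryophyte	Undetermined	Moss								L:17
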