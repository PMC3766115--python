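phylum	taxgroup	genomes	sites	regulogs	target_genes
Firmicutes	Lactobacillaceae	15	581	39	1074
Firmicutes	Streptococcaceae	15	400	29	881
Firmicutes	Bacillales	11	668	39	1525
Firmicutes	Staphylococcaceae	7	288	30	647
Firmicutes	Clostridiaceae	20	958	40	2036
Bacteroidae	Bacteroidaceae	11	84	2	334
Chlorobia	Chlorobiales	11	73	6	263
Actinobacteria	Corynebacteriaceae	8	80	13	194
Actinobacteria	Mycobacteriaceae	9	131	12	247
Cyanobacteria	Cyanobacteria	14	86	11	150
Chloroflexi	Chloroflexi	5	98	17	300
Deinococcus-Thermus	Deinococcus-Thermus	5	64	13	221
Thermotogae	Thermotogales	11	88	13	379
Proteobacteria/Delta	Desulfovibrionales	10	78	9	159
Proteobacteria/Alpha	Caulobacterales	4	36	8	70
Proteobacteria/Alpha	Rhodobacterales	15	182	13	443
Proteobacteria/Alpha	Rhizobiales	15	221	11	486
Proteobacteria/Beta	Burkholderia	8	127	9	319
Proteobacteria/Beta	Ralstonia	6	66	10	173
Proteobacteria/Gamma	Enterobacteriales	12	188	18	601
Proteobacteria/Gamma	Pasteurellales	9	112	11	258
Proteobacteria/Gamma	Vibrionales	10	202	17	533
Proteobacteria/Gamma	Pseudomonadaceae	8	92	9	248
Proteobacteria/Gamma	Shewanellaceae	16	291	15	910
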