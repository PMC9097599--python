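patient_id	age_at_lm	sex	driver_alteration	ecog_ps	extracranial_status	brain_parenchymal_status	tki_history	os_months	profiling_test
P01	48	man	EGFR.G719C	2	stable	stable	Icotinib+Erlotinib	16	180 genes panel and WGS
P02	46	man	EGFR.L858R	4	progressive	progressive	Icotinib+Osimertinib	2	180 genes panel and WGS
P03	56	man	EML4-ALK fusion	2	stable	without metastases	Crizotinib+Brigatinib	3	137 genes panel
P04	54	man	EGFR.exon19del	1	stable	without metastases	Gefitinib+Osimertinib+ Erlotinib	16	180 genes panel and WGS
P05	47	man	EGFR.exon19del	1	stable	without metastases	Icotinib	>14	180 genes panel and WGS
P06	62	woman	EGFR.L858R	3	stable	stable	Erlotinib+Osimertinib	12	520 genes panel
P07	75	man	EGFR.L858R	3	stable	without metastases	Erlotinib	11	137 genes panel
P08	49	woman	EGFR.exon19del	2	progressive	regressive	Gefitinib+Osimertinib+ Capmatinib	8	180 genes panel and WGS
P09	45	woman	EGFR.exon19del	2	stable	progressive	Gefitinib	>11	180 genes panel and WGS
P10	57	man	EGFR.exon19del	3	stable	without metastases	Gefitinib+Osimertinib	>13	180 genes panel and WGS
P11	48	woman	EGFR.exon19del	4	stable	progressive	Gefitinib+Osimertinib	15	180 genes panel and WGS
P12	47	woman	EGFR.L858R	3	without metastases	without metastases	Icotinib+Osimertinib+ Erlotinib+Cabozantinib	>19	180 genes panel and WGS
P13	57	woman	ERBB2.G776delinsVV	3	stable	progressive	Afatinib	6	520 genes panel
P14	58	woman	EGFR.exon19del	2	progressive	progressive	Gefitinib+Erlotinib	1	180 genes panel and WGS
P15	48	man	EGFR.L858R	4	progressive	stable	Erlotinib+Osimertinib	7	520 genes panel
P16	56	woman	EGFR.exon19del	1	progressive	without metastases	Gefitinib	>13	180 genes panel and WGS
P17	52	woman	EGFR.exon19del	2	stable	stable	Gefitinib+Osimertinib	>14	180 genes panel and WGS
P18	60	man	EGFR.L858R	3	progressive	stable	Icotinib+Erlotinib+ Osimertinib	3	180 genes panel and WGS
P19	53	man	EGFR.L858R	2	without metastases	progressive	Icotinib	6	137 genes panel
P20	39	man	EGFR.exon19del	2	regressive	without metastases	Gefitinib+Afatinib	>14	180 genes panel and WGS
P21	66	woman	EGFR.L858R	4	progressive	stable	Gefitinib+Osimertinib	0.5	180 genes panel and WGS
P22	60	woman	EGFR.L858R	1	stable	progressive	Gefitinib+Erlotinib+ Osimertinib	8	520 genes panel
P23	60	man	EGFR.L858R	3	progressive	progressive	Gefitinib	9	520 genes panel
P24	62	woman	EGFR.exon19del	2	progressive	without metastases	Gefitinib+Erlotinib	9	137 genes panel
P25	55	man	EGFR.exon19del	1	stable	progressive	Gefitinib+Erlotinib+ Osimertinib	8	180 genes panel and WGS
P26	50	woman	EGFR.L858R	2	stable	stable	Osimertinib	>12	180 genes panel and WGS
P27	64	woman	EGFR.exon19del	2	stable	progressive	Erlotinib	>11	180 genes panel and WGS
P28	79	man	EGFR.L858R	2	stable	without metastases	Icotinib	>9	180 genes panel and WGS
P29	50	woman	EGFR.exon19del	2	progressive	progressive	–	11	180 genes panel and WGS
P30	47	man	EGFR.exon19ins	1	progressive	progressive	Gefitinib+Afatinib+ Osimertinib	5	180 genes panel and WGS
P31	64	woman	EGFR.L858R	2	progressive	progressive	–	10	180 genes panel and WGS
P32	66	man	EGFR.L858R	4	stable	stable	Afatinib	3.5	180 genes panel and WGS
P34	60	man	EGFR.L858R	1	progressive	progressive	Gefitinib+Erlotinib	>7	180 genes panel and WGS
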