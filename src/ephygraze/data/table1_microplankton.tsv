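taxon_id	name	group	biovolume_um3	carbon_model	abundance_t0	abundance_t0_sd	biomass_t0_x10ugC	biomass_t0_sd	ingestion_cells	ingestion_cells_sd	ingestion_carbon_x10ugC	ingestion_carbon_sd
ceratium_furca	Ceratium furca	Dinophyceae	73236	non_diatom	31.5	7.8	2.52	0.62	9.9	1.0	0.79	0.08
ceratium_kofoidii	Ceratium kofoidii	Dinophyceae	12747	non_diatom	151	14.1	2.34	0.22	20.2	5.7	0.31	0.09
dinophysis_fortii	Dinophysis fortii	Dinophyceae	80953	non_diatom	5.0	1.4	0.44	0.12	1.0	0.0	0.06	0.05
gonyaulax_sp	Gonyaulax sp.	Dinophyceae	134628	non_diatom	17.5	4.9	2.48	0.70	4.2	0.8	0.59	0.11
oxytoxum_caudatum	Oxytoxum caudatum	Dinophyceae	8177	non_diatom	3.5	0.7	0.04	0.01	0.9	0.3	0.01	0.01
prorocentrum_micans	Prorocentrum micans	Dinophyceae	43960	non_diatom	19	9.9	0.94	0.49	4.7	1.7	0.23	0.08
dinophyceae_undet	Dinophyceae undet.	Dinophyceae	58875	non_diatom	4.0	2.8	0.26	0.18	2.5	0.4	0.16	0.03
ciliophora_a1	Ciliophora (A1)	AloricateCiliate	14137	non_diatom	34.5	13.4	0.59	0.23	5.0	0.5	0.09	0.01
ciliophora_a2	Ciliophora (A2)	AloricateCiliate	65450	non_diatom	10.5	2.1	0.75	0.15	2.5	0.9	0.18	0.06
strombidiidae_c1	Strombidiidae (C1)	AloricateCiliate	3142	non_diatom	20	4.2	0.08	0.02	8.2	0.7	0.03	0.00
strombidiidae_c2	Strombidiidae (C2)	AloricateCiliate	14544	non_diatom	31	9.9	0.54	0.17	12.1	0.8	0.21	0.01
favella_sp	Favella sp.	Tintinnid	13901	non_diatom	60.5	10.6	1.02	0.18	13.8	3.0	0.23	0.05
stenosemella_nivalis	Stenosemella nivalis	Tintinnid	14137	non_diatom	101.5	21.9	1.73	0.37	38.2	2.4	0.65	0.04
tintinnopsis_e1	Tintinnopsis sp. (E1)	Tintinnid	4712	non_diatom	49.5	9.2	0.30	0.06	14.6	2.5	0.09	0.02
tintinnopsis_e2	Tintinnopsis sp. (E2)	Tintinnid	21817	non_diatom	19.5	12.0	0.50	0.31	7.9	1.2	0.20	0.03
tintinnopsis_e3	Tintinnopsis sp. (E3)	Tintinnid	59865	non_diatom	3.5	2.1	0.23	0.14	1.9	0.1	0.13	0.01
copepod_nauplii	Copepod nauplii	Metazoa	176625	non_diatom	10.0	0.0	1.83	0.00	2.2	0.5	0.27	0.24
calciosolenia_murray	Calciosolenia murray	Coccolithophyceae	4091	diatom	50.5	38.9	0.12	0.10	5.7	0.4	0.01	0.00
cocconeis_sp	Cocconeis sp.	Coccolithophyceae	2322	diatom	38.5	14.8	0.06	0.02	6.6	2.1	0.01	0.00
diploneis_sp	Diploneis sp.	Bacillariophyceae	7800	diatom	29.0	24.0	0.12	0.10	7.7	0.4	0.03	0.00
navicula_sp	Navicula sp.	Bacillariophyceae	4377	diatom	85.0	7.1	0.22	0.02	15.0	0.5	0.04	0.00
bacillariophyceae_undet	Bacillariophyceae undet.	Bacillariophyceae	8450	diatom	248	31.1	1.09	0.14	34.5	11.3	0.15	0.05
pseudonitzschia_sp	Pseudonitzschia sp.	Bacillariophyceae	2500	diatom	142	39.6	0.23	0.06	36.4	3.8	0.06	0.01
pleurosigma_sp	Pleurosigma sp.	Bacillariophyceae	10838	diatom	126	31.1	0.68	0.17	23.2	7.9	0.12	0.04
chaetoceros_sp	Chaetoceros sp.	Mediophyceae	4352	diatom	11.5	2.1	0.03	0.01	4.4	1.6	0.01	0.00
leptocylindrus_sp	Leptocylindrus sp.	Mediophyceae	7850	diatom	167	72.1	0.69	0.30	42.8	0.5	0.18	0.00
fragilaria_sp	Fragilaria sp.	Fragilariophyceae	1313	diatom	59.0	38.2	0.06	0.04	28.1	0.0	0.03	0.00
guinardia_striata	Guinardia striata	Coscinodiscophyceae	49063	diatom	11.5	14.8	0.21	0.27	3.9	0.3	0.07	0.01
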