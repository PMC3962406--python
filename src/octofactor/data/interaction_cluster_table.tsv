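accession	protein_name	gene_symbol	function	116:114 log2R	116:114 p	121:114 log2R	121:114 p	printed_section	printed_cluster
B2KGV2	Carbamoyl-phosphate synthase	Cps1	fatty acid metabolism	3.11	0.008	1.67	0.092	lower_right	2
A2ATU0	Probable 2-oxoglutarate dehydrogenase E1	Dhtkd1	alcohol metabolism	3.10	0.003	1.62	0.004	lower_right	2
P10649	Glutathione S-transferase Mu 1	Gstm1	oxidation reduction	2.92	0.000	-0.31	0.967	lower_right	3
Q8R0Y6	10-formyltetrahydrofolate dehydrogenase	Aldh1l1	oxidation reduction	2.55	0.001	0.07	0.529	lower_right	2
Q3UER1	Fructose-bisphosphate aldolase	Aldob	alcohol metabolism	2.09	0.000	0.76	0.303	lower_right	2
Q91XG2	Cytochrome P450, family 2A4	Cyp2a4	oxidation reduction	2.07	0.038	0.76	0.211	lower_right	2
Q3UKT3	Putative uncharacterized protein	Oat	amino acid metabolism	1.87	0.001	0.61	0.737	lower_right	2
Q544B1	Aldehyde dehydrogenase 2	Aldh2	alcohol metabolism	1.79	0.000	0.69	0.064	lower_right	2
A2A6J8	Troponin I, skeletal, fast 2	Tnni2	developmental process	1.57	0.003	-0.01	0.007	lower_right	2
Q91XD4	Formimidoyltransferase-cyclodeaminase	Ftcd	fatty acid metabolism	1.45	0.005	0.00	0.732	lower_right	2
P37040	NADPH-cytochrome P450 reductase	Por	oxidation reduction	1.44	0.037	0.32	0.615	lower_right	2
Q566C3	Alanine aminotransferase 1	Gpt	amino acid metabolism	1.40	0.012	-0.32	0.766	lower_right	2
Q6GTG6	Long-chain-fatty-acid-CoA ligase 1	Acsl1	fatty acid metabolism	1.29	0.009	-1.79	0.043	lower_right	3
Q05421	Cytochrome P450 2E1	Cyp2e1	oxidation reduction	1.26	0.001	-4.29	0.034	lower_right	3
P08249	Malate dehydrogenase	Mdh2	oxidation reduction	1.06	0.024	-0.15	0.571	lower_right	2
Q9CZN7	Serine hydroxymethyltransferase	Shmt2	fatty acid metabolism	1.02	0.040	-0.29	0.818	lower_right	2
P15105	Glutamine synthetase	Glul	fatty acid metabolism	1.01	0.001	-0.45	0.045	lower_right	2
P19157	Glutathione S-transferase P 1	Gstp1	oxidation reduction	0.90	0.011	-1.40	0.000	lower_right	2
Q8QZS6	3-hydroxy-3-methylglutaryl-Coenzyme A lyase	Hmgcl	fatty acid metabolism	0.76	0.008	-1.32	0.257	lower_right	2
Q9QXE0	2-hydroxyacyl-CoA lyase 1	Hacl1	fatty acid metabolism	0.72	0.039	-0.96	0.135	lower_right	2
P54869	Hydroxymethylglutaryl-CoA synthase	Hmgcs2	alcohol metabolism	0.72	0.000	-0.73	0.001	lower_right	2
P08228	Superoxide dismutase [Cu-Zn]	Sod1	oxidation reduction	0.45	0.938	-1.71	0.001	lower_right	2
P40142	Transketolase	Tkt	fatty acid metabolism	0.37	0.188	-1.40	0.040	lower_right	2
Q3TV75	Putative uncharacterized protein	Uqcrc1	oxidation reduction	0.35	0.323	-1.44	0.031	lower_right	2
Q540D7	Aldehyde reductase	Akr1a4	alcohol metabolism	0.24	0.434	-0.89	0.032	lower_right	2
Q80XN0	D-beta-hydroxybutyrate dehydrogenase	Bdh1	oxidation reduction	0.19	0.517	-1.01	0.005	lower_right	2
Q8VC30	FAD-AMP lyase (cyclizing)	Dak	alcohol metabolism	0.16	0.230	-2.43	0.005	lower_right	2
Q63880	Liver carboxylesterase 31	Es31	alcohol metabolism	0.09	0.959	-2.19	0.001	lower_right	2
Q3THH1	Putative uncharacterized protein	Pdia6	oxidation reduction	0.01	0.804	-1.37	0.029	lower_right	2
Q3UEM0	MCG9091, isoform CRA_d	Akr1c6	fatty acid metabolism	-0.04	0.223	-1.59	0.001	lower_right	2
Q9QXD6	Fructose-1,6-bisphosphatase 1	Fbp1	fatty acid metabolism	-0.09	0.344	-2.35	0.002	lower_right	2
Q9WVL0	Maleylacetoacetate isomerase	Gstz1	oxidation reduction	-0.17	0.653	-2.42	0.012	lower_right	2
Q5FW57	Glycine N-acyltransferase-like protein	Gm4952	fatty acid metabolism	-0.24	0.299	-1.93	0.050	lower_right	2
Q9CPY7	Cytosol aminopeptidase	Lap3	metabolism	-0.25	0.255	-2.33	0.000	lower_right	2
Q3T9Z2	Glyoxylate reductase	Grhpr	oxidation reduction	-0.27	0.276	-2.05	0.012	lower_right	2
Q91W49	Enoyl-Coenzyme A, hydratase	Ehhadh	oxidation reduction	-0.31	0.091	-2.29	0.000	lower_right	2
Q91XE0	Glycine N-acyltransferase	Glyat	fatty acid metabolism	-0.52	0.426	-1.65	0.011	lower_right	2
P48036	Annexin A5	Anxa5	fatty acid metabolism	-0.60	0.220	-2.09	0.011	lower_right	2
Q542K4	Catalase	Cat	oxidation reduction	-0.78	0.001	-2.62	0.000	lower_right	2
B2RTM0	Histone H4	hist2h4	DNA binding	-1.10	0.098	-2.58	0.046	lower_right	2
P16015	Carbonic anhydrase 3	Ca3	fatty acid metabolism	-2.14	0.000	-3.43	0.000	lower_right	2
P52503	NADH dehydrogenase iron-sulfur protein 6	Ndufs6	oxidation reduction	-0.01	1.000	1.17	0.048	upper_left	2
Q58E70	Putative uncharacterized protein	Krt8	developmental process	-0.86	0.046	0.40	0.095	upper_left	2
Q5FW97	Enolase	Eno1	alcohol metabolism	-1.83	0.000	-0.17	0.056	upper_left	2
B1ASG5	Ubiquinol-cytochrome c reductase hinge protein	Uqcrh	oxidation reduction	-2.91	0.183	1.61	0.039	upper_left	3
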