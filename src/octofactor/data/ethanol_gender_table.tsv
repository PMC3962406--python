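accession	protein_name	gene_symbol	function	116:114 log2R	115:113 log2R
B2KGV2	Carbamoyl-phosphate synthase	Cps1	fatty acid metabolism	3.11	-
A2ATU0	Probable 2-oxoglutarate dehydrogenase E1	Dhtkd1	alcohol metabolism	3.1	-
P10649	Glutathione S-transferase Mu 1	Gstm1	oxidation reduction	2.92	1.37
A0ZNJ2	3-hydroxyisobutyrate dehydrogenase	Hibadh	oxidation reduction	2.76	-
Q8R0Y6	10-formyltetrahydrofolate dehydrogenase	Aldh1l1	oxidation reduction	2.55	-
Q3UER1	Fructose-bisphosphate aldolase	Aldob	alcohol metabolism	2.09	-
Q91XG2	Cytochrome P450, family 2A4	Cyp2a4	oxidation reduction	2.07	-
Q3UWN2	Putative uncharacterized protein	Aass	oxidation reduction	2.01	-
Q7TSZ0	Heat shock protein 9	Hspa9	chaperone	2.01	-
Q3UJ34	Argininosuccinate synthase	Ass1	oxidation reduction	1.95	-
Q3UKT3	Putative uncharacterized protein	Oat	amino acid metabolism	1.87	-
Q544B1	Aldehyde dehydrogenase 2	Aldh2	alcohol metabolism	1.79	-
Q546G4	Albumin 1	Krt8	developmental process	1.63	2.07
Q3TCQ3	Putative uncharacterized protein	Pcx	energy production	1.57	-
A2A6J8	Troponin I, skeletal, fast 2	Tnni2	developmental process	1.57	2.21
Q91XD4	Formimidoyltransferase-cyclodeaminase	Ftcd	fatty acid metabolism	1.45	-1.69
P37040	NADPH-cytochrome P450 reductase	Por	oxidation reduction	1.44	-
B1AWX7	Aldehyde dehydrogenase 1B1	Aldh1b1	alcohol metabolism	1.42	-
Q566C3	Alanine aminotransferase 1	Gpt	amino acid metabolism	1.4	-
Q3TIT9	Acetyl-Coenzyme A acyltransferase 2	Acaa2	fatty acid metabolism	1.37	-
Q921I1	Serotransferrin	Tf	serum carrier protein	1.37	1.9
D3Z106	Uncharacterized protein	Acsm1	fatty acid metabolism	1.36	-
Q6GTG6	Long-chain-fatty-acid-CoA ligase 1	Acsl1	fatty acid metabolism	1.29	-
Q05421	Cytochrome P450 2E1	Cyp2e1	oxidation reduction	1.26	1.59
Q8R086	Sulfite oxidase, mitochondrial	Suox	oxidation reduction	1.24	-
P63038	60 kDa heat shock protein	Hspd1	chaperone	1.14	-
P08249	Malate dehydrogenase	Mdh2	oxidation reduction	1.06	1.49
Q9CZN7	Serine hydroxymethyltransferase	Shmt2	fatty acid metabolism	1.02	-
P15105	Glutamine synthetase	Glul	fatty acid metabolism	1.01	-
Q3TXS9	Putative uncharacterized protein	Rps2	DNA binding	-1.29	-2.51
Q3U6S1	Putative uncharacterized protein	Vim	developmental process	-1.55	-1.38
Q5FW97	Enolase	Eno1	alcohol metabolism	-1.83	-1.17
P32020	Non-specific lipid-transfer protein	Scp2	fatty acid metabolism	-1.97	-
P10853	Histone H2B type 1-F	Hist1h2bf	DNA binding	-1.98	-3.89
P16015	Carbonic anhydrase 3	Ca3	fatty acid metabolism	-2.14	-4.98
Q91W60	Inter alpha-trypsin inhibitor, heavy chain 4	Itih4	metabolism	-	4.33
Q545Y3	Putative uncharacterized protein	Tpm1	developmental process	-	2.99
A2A4Z2	Troponin C2, fast	Tnnc2	developmental process	-	2.92
Q8CF02	Protein FAM25	Fam25	N/A	-	2.29
Q02819	Nucleobindin-1	Nucb1	DNA binding	-	2.01
P56135	ATP synthase-coupling factor 6	Atp5j	energy production	-	1.93
P63242	Eukaryotic translation initiation factor 5A-1	Eif5a	apoptosis process	-	1.85
Q5FWJ5	Hnrpk protein	actg1-b	DNA binding	-	1.83
Q8C7E7	Starch-binding domain-containing protein 1	Stbd1	amino acid metabolism	-	1.71
Q8VDD5	Myosin-9	Myh9	developmental process	-	1.65
Q58E70	Putative uncharacterized protein	Krt8	developmental process	-	1.54
P27773	Protein disulfide-isomerase A3	Pdia3	oxidation reduction	-	1.51
Q3UKP2	Hemopexin, isoform CRA_f	Hpx	signaling/transcription	-	1.47
Q91XF8	Apolipoprotein A-IV	Apoa4	fatty acid metabolism	-	1.46
Q544Y7	Cofilin 1, non-muscle	Cfl1	developmental process	-	1.41
Q4KL76	Heat shock protein 1 (Chaperonin 10)	Hspe1	chaperone	-	1.4
Q922C8	Prolyl 4-hydroxylase, beta polypeptide	P4hb	oxidation reduction	-	1.36
Q3UEK9	Alpha-2-HS-glycoprotein, isoform CRA_a	Ahsg	developmental process	-	1.32
Q99K47	Fibrinogen, alpha polypeptide	Fga	signaling/transcription	-	1.28
P19157	Glutathione S-transferase P 1	Gstp1	oxidation reduction	-	1.28
E0CXN5	Uncharacterized protein	Gpd1	oxidation reduction	-	1.25
Q9CQB4	MCG67985	Uqcrb	oxidation reduction	-	1.22
A8DUK0	Beta-globin	Hbb-b1	transport	-	1.2
Q4FJX9	Superoxide dismutase	Sod2	oxidation reduction	-	1.1
Q54AH9	Beta-2-globin (Fragment)	Hbb	transport	-	1.08
B2RXY7	Carbonyl reductase 1	Cbr1	oxidation reduction	-	1.02
Q9DCY1	Peptidyl-prolyl cis-trans isomerase	Ppib	protein folding	-	-1.02
Q91V38	Heat shock protein 90, beta (Grp94)	Hsp90b1	chaperone	-	-1.06
Q3TZJ3	Putative uncharacterized protein	Hspa8	chaperone	-	-1.16
D2KHZ9	Glyceraldehyde-3-phosphate dehydrogenase	Gapdh	oxidation reduction	-	-1.28
P62264	40S ribosomal protein S14	Rps14	signaling/transcription	-	-1.3
Q3TDN8	Putative uncharacterized protein	Bphl	signaling/transcription	-	-1.34
P14152	Malate dehydrogenase	Mdh1	oxidation reduction	-	-1.37
Q9JMH6	Thioredoxin reductase 1	Txnrd1	oxidation reduction	-	-1.37
P49429	4-hydroxyphenylpyruvate dioxygenase	Hpd	oxidation reduction	-	-1.58
O88844	Isocitrate dehydrogenase [NADP]	Idh1	oxidation reduction	-	-1.63
Q3V2F7	Fatty acid binding protein 1, liver	Fabp1	fatty acid metabolism	-	-1.74
Q3U9G2	Putative uncharacterized protein	Hspa5	chaperone	-	-1.75
Q3TY87	Putative uncharacterized protein	Fah	amino acid metabolism	-	-1.77
Q99JY0	Trifunctional enzyme subunit beta	Hadhb	oxidation reduction	-	-1.78
Q4FZE6	Putative uncharacterized protein	Rps7	signaling/transcription	-	-1.9
P05784	Keratin, type I cytoskeletal 18	Krt18	developmental process	-	-1.97
P17563	Selenium-binding protein 1	Selenbp1	signaling/transcription	-	-1.98
Q5EBH4	Dimethylglycine dehydrogenase	Dmgdh	oxidation reduction	-	-2.06
Q99KR3	Beta-lactamase-like protein 2	Lactb2	fatty acid metabolism	-	-2.21
Q53ZU7	Peroxiredoxin 6	Prdx6	oxidation reduction	-	-2.3
Q5M9M5	MCG10806	Rpl23a	DNA binding	-	-2.62
O35459	Betaine-homocysteine S-methyltransferase 1	Bhmt	amino acid metabolism	-	-2.74
Q3UIA9	Fumarate hydratase 1	Fh1	fatty acid metabolism	-	-2.87
Q63880	Liver carboxylesterase 31	Es31	alcohol metabolism	-	-3.19
Q56A15	Cytochrome c, somatic	Cycs	energy production	-	-3.22
Q3V235	Prohibitin 2	Phb2	DNA binding	-	-3.22
P67778	Prohibitin	Phb	DNA binding	-	-3.43
P56480	ATP synthase subunit beta	Atp5b	energy production	-	-3.6
Q03265	ATP synthase subunit alpha	Atp5a1	energy production	-	-3.79
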