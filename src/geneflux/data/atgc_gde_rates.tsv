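atgc	genera	gain_site	gain_gene	loss_site	loss_gene	expansion_site	expansion_gene	reduction_site	reduction_gene
ATGC001	Enterobacteria	18563	17.3	50517	47.1	1864	1.7	4405	4.1
ATGC002	Enterobacter-Klebsiella	25866	24.5	6448	6.1	1914	1.8	237	0.2
ATGC003	Streptococcus	11894	11.8	53500	53.0	1368	1.4	5092	5.0
ATGC004	Streptococcus	5633	5.5	29233	28.5	1601	1.6	2984	2.9
ATGC005	Streptococcus	11940	11.3	42215	40.0	3755	3.6	2380	2.3
ATGC014	Bacillus	25485	25.5	77488	77.7	3895	3.9	6908	6.9
ATGC015	Bacillus	6521	6.6	25293	25.5	804	0.8	1343	1.4
ATGC021	Chlamydia	16346	14.0	25968	22.3	419	0.4	240	0.2
ATGC022	Chlamydia-Chlamydophila	5434	5.2	11202	10.8	1213	1.2	524	0.5
ATGC025	Mycobacterium	50823	45.9	74868	67.6	5109	4.6	3708	3.3
ATGC033	Mycoplasma	5865	4.6	8335	6.6	2484	2.0	548	0.4
ATGC046	Rickettsia	6677	7.4	23674	26.4	325	0.4	750	0.8
ATGC052	Helicobacter	3733	3.6	8293	8.0	288	0.3	974	0.9
ATGC054	Staphylococcus	21512	19.9	146937	135.8	2924	2.7	21696	20.1
ATGC056	Lactobacillus	3417	3.3	17553	17.2	1094	1.1	314	0.3
ATGC067	Corynebacterium	10013	9.0	146236	131.5	1582	1.4	734	0.7
ATGC068	Corynebacterium	5338	4.9	82891	76.0	2335	2.1	4414	4.0
ATGC072	Pseudomonas	10467	9.2	25516	22.5	2162	1.9	1766	1.6
ATGC082	Clostridium	7223	6.6	82676	75.8	3745	3.4	1030	0.9
ATGC089	Burkholderia	39593	35.5	252406	226.3	4988	4.5	3417	3.1
ATGC090	Burkholderia	15276	13.6	54192	48.2	4582	4.1	1644	1.5
ATGC094	Sulfolobus	5956	6.1	42639	43.4	3931	4.0	1643	1.7
ATGC105	Bifidobacterium	10383	8.3	11148	9.0	655	0.5	817	0.7
ATGC106	Bifidobacterium	11039	8.9	16473	13.3	742	0.6	812	0.7
ATGC109	Listeria	7650	7.5	3411	3.4	551	0.5	207	0.2
ATGC121	Shewanella	8576	7.3	5340	4.5	973	0.8	348	0.3
ATGC128	Yersinia	20234	17.5	39460	34.2	2391	2.1	2369	2.1
ATGC135	Xanthomonas	13993	12.2	31495	27.4	3413	3.0	1518	1.3
ATGC137	Brucella-Ochrobactrum	16268	15.6	25177	24.1	1968	1.9	1033	1.0
ATGC138	Neisseria	7278	6.4	29817	26.4	990	0.9	2638	2.3
ATGC139	Francisella	2324	2.0	9075	7.7	546	0.5	401	0.3
ATGC144	Campylobacter	14997	14.6	6085	5.9	1365	1.3	109	0.1
ATGC153	Acinetobacter	5416	5.1	54454	51.7	3747	3.6	2029	1.9
ATGC163	Propionibacterium	2948	2.7	13223	12.0	446	0.4	145	0.1
ATGC186	Legionella	2082	1.9	99232	89.9	3546	3.2	1647	1.5
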