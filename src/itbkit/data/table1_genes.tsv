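# Vertebrate beta-integrin and nematode beta-integrin-like genes and proteins.
# Coordinates are transcribed verbatim as printed (chromosome:start-end, 1-based
# inclusive); some printed gene sizes disagree with their own coordinates, and
# some rows print start/end in descending (strand) order. The loader computes
# the span from the coordinates and marks each row self_consistent or not.
# printed_kb "na" means the source table gave no usable coordinates for the row.
animal	species	gene	gene_symbol	coordinates	printed_kb	coding_exons	strand	subunit_mw	amino_acids	ncbi_id	uniprot_id	family
Human	Homo sapiens	ITB1	ITGB1	10:33,190,501-33,224,486	35.2	16	-	88415	798	NM_002211	P05556	ITB1
Mouse	Mus musculus	Itb1	Itgb1	8:131,209,552-131,257,438	47.9	15	+	88231	798	NM_010578	P09055	ITB1
Horse	Equus caballus	ITB1	ITGB1	29:5,050,336-5,076,608	26.3	15	+	88202	798	XP_001492715	na	ITB1
Opossum	Monodelphis domestica	ITB1	ITGB1	8:240,074,436-240,104,533	30.1	15	+	88329	799	XP_001366567	na	ITB1
Chicken	Gallus gallus	ITB1	ITGB1	2:13,977,440-14,000,322	22.9	15	+	88554	803	NP_001034343	P07228	ITB1
Frog	Xenopus tropicalis	ITB1	ITGB1	503:452,582-465,188	12.6	15	+	88083	798	NP_989160	Q6P4X1	ITB1
Zebrafish	Danio rerio	ITB1A	ITGB1A	24:1,010,009-1,028,526	18.5	15	-	88592	798	NP_001030143	Q3YAA1	ITB1
Zebrafish	Danio rerio	ITB1B	ITGB1B	2:42,692,236-42,708,345	16.1	15	+	86570	787	NP_001030151	Q3YA99	ITB1
Human	Homo sapiens	ITB2	ITGB2	21:46,306,286-46,330,697	40.0	15	-	84782	769	NM_001127491	P05107	ITB2
Mouse	Mus musculus	Itb2	Itgb2	10:76,993,093-77,028,419	35.3	15	+	85026	771	NM_008404	P11835	ITB2
Mouse	Mus musculus	Itb2l	Itgb2l	16:96,643,905-96,665,221	21.3	15	-	81547	738	NM_008405	Q3UV74	ITB2
Horse	Equus caballus	ITB2A	ITGB2A	26:39,992,918-40,009,865	16.9	15	-	85290	770	XP_001490052	na	ITB2
Horse	Equus caballus	ITB2B	ITGB2B	26:40,054,164-40,069,857	15.7	14	-	79824	726	chr26.199.1	na	ITB2
Opossum	Monodelphis domestica	ITB2	ITGB2	2:539,079,162-539,090,540	11.4	13	-	83015	761	chr2.11.580.a	na	ITB2
Chicken	Gallus gallus	ITB2	ITGB2	7:7,143,899-7,150,094	6.2	15	-	85409	772	NP_990582	na	ITB2
Frog	Xenopus tropicalis	ITB2	ITGB2	2185:1,356,257-1,405,734	49.5	16	-	86980	782	XP_002936570	na	ITB2
Zebrafish	Danio rerio	ITB2	ITGB2	9:47,603,423-47,619,406	16.0	15	+	84519	768	XP_686012	na	ITB2
Human	Homo sapiens	ITB3	ITGB3	17:45,331,228-45,387,567	37.4	9	+	87058	788	NM_000212	P05106	ITB3
Mouse	Mus musculus	Itb3	Itgb3	11:104,469,370-104,528,689	59.3	15	+	86694	787	NM_016780	O54890	ITB3
Horse	Equus caballus	ITB3	ITGB3	11:17,206,504-17,237,153	30.7	15	-	86360	784	NM_001081802	na	ITB3
Opossum	Monodelphis domestica	ITB3	ITGB3	2:208,102,619-208,154,477	51.9	14	+	84497	764	chr2.5.154.a	na	ITB3
Chicken	Gallus gallus	ITB3	ITGB3	27:2,207,723-2,223,943	16.2	15	+	86088	781	NP_989646	na	ITB3
Frog	Xenopus tropicalis	ITB3	ITGB3	973:169,881-200,256	30.4	15	-	88235	792	XP_002942401	na	ITB3
Zebrafish	Danio rerio	ITB3A	ITGB3A	3:16,152,931-16,181,252	28.3	15	+	85693	785	NP_001032312	Q3LTM4	ITB3
Zebrafish	Danio rerio	ITB3B	ITGB3B	12:21,495,417-21,520,656	25.2	15	-	87700	790	NP_001076417	B3DIP9	ITB3
Human	Homo sapiens	ITB4	ITGB4	17:73,720,784-73,753,633	36.4	39	+	202167	1822	NM_000213	P16144	ITB4
Mouse	Mus musculus	Itb4	Itgb4	11:115,836,039-115,869,725	33.7	39	+	201650	1818	NM_133663	A2A863	ITB4
Horse	Equus caballus	ITB4	ITGB4	11:6,286,192-6,312,590	26.4	39	-	194864	1752	XP_001915915	na	ITB4
Opossum	Monodelphis domestica	ITB4	ITGB4	2:213,276,209-213,319,767	43.6	36	-	198824	1778	XP_001377606	na	ITB4
Chicken	Gallus gallus	ITB4	ITGB4	18:4,713,504-4,732,758	19.3	39	-	203330	1818	E1C9G7	E1C9G7	ITB4
Frog	Xenopus tropicalis	ITB4	ITGB4	545:495,511-545,134	49.6	38	+	204208	1835	XP_002940020	na	ITB4
Zebrafish	Danio rerio	ITB4	ITGB4	8:13,034,599-13,080,896	46.3	39	+	210736	1893	NP_001019557	Q4U0S1	ITB4
Human	Homo sapiens	ITB5	ITGB5	3:124,482,473-124,605,847	139.5	15	-	88054	799	BC006541	P18084	ITB5
Mouse	Mus musculus	Itb5	Itgb5	3:126,102,954-125,963,482	139.5	15	+	87909	798	NM_010580	O70309	ITB5
Horse	Equus caballus	ITB5	ITGB5	19:34,769,099-34,876,312	107.2	15	+	87985	803	XP_001500077	na	ITB5
Opossum	Monodelphis domestica	ITB5	ITGB5	4:90,575,064-90,751,974	17.7	14	-	86072	779	XP_001372711	na	ITB5
Chicken	Gallus gallus	ITB5	ITGB5	7:29,463,064-29,500,494	37.4	15	-	88475	812	NP_989814	na	ITB5
Frog	Xenopus tropicalis	ITB5	ITGB5	na	na	na	na	87561	807	NP_001135704	B5DEV6	ITB5
Zebrafish	Danio rerio	ITB5	ITGB5	9:22,031,538-22,101,156	69.6	16	+	88956	802	NP_001076305	A5D6V1	ITB5
Human	Homo sapiens	ITB6	ITGB6	2:160,958,250-161,056,574	172.2	15	-	85936	788	NM_000888	P18564	ITB6
Mouse	Mus musculus	Itb6	Itgb6	2:160,836,644-160,664,416	172.2	15	+	86042	787	NM_021359	Q9Z0T9	ITB6
Horse	Equus caballus	ITB6	ITGB6	18:40,790,052-40,860,613	70.6	15	-	85817	788	XP_001492914	na	ITB6
Opossum	Monodelphis domestica	ITB6	ITGB6	4:165,626,656-165,720,419	93.8	15	-	86274	787	ENSMODT6582	na	ITB6
Chicken	Gallus gallus	ITB6	ITGB6	7:23,382,214-23,409,883	27.7	15	+	86530	789	XP_422037	E1C6K8	ITB6
Frog	Xenopus tropicalis	ITB6	ITGB6	51:1,605,719-1,638,193	32.5	13	+	76152	696	NP_001090775	A4IGI8	ITB6
Human	Homo sapiens	ITB7	ITGB7	12:53,585,343-53,594,227	16.3	15	-	86903	798	NM_000889	P26010	ITB7
Mouse	Mus musculus	Itb7	Itgb7	15:102,046,428-102,062,317	15.9	15	-	87411	806	NM_013566	P26011	ITB7
Horse	Equus caballus	ITB7	ITGB7	6:70,193,060-70,201,400	8.3	14	-	86666	797	XP_001494917	na	ITB7
Frog	Xenopus tropicalis	ITB7	ITGB7	226:1,387,775-1,412,224	24.5	15	+	84461	766	XP_002936686	na	ITB7
Zebrafish	Danio rerio	ITB7	ITGB7	6:43,251,691-43,271,173	19.5	15	-	74006	661	XP_001337949	na	ITB7
Human	Homo sapiens	ITB8	ITGB8	7:20,371,430-20,449,617	85.1	14	+	85632	769	NM_002214	P26012	ITB8
Mouse	Mus musculus	Itb8	Itgb8	12:120,477,276-120,396,490	80.8	14	-	84519	767	NM_177290	Q0VDB0	ITB8
Horse	Equus caballus	ITB8	ITGB8	4:52,216,892-52,290,256	73.4	14	+	85361	767	XP_001497271	na	ITB8
Opossum	Monodelphis domestica	ITB8	ITGB8	8:302,826,175-302,899,169	73.0	14	-	83721	757	XP_001371834	na	ITB8
Chicken	Gallus gallus	ITB8	ITGB8	2:30,002,182-30,052,908	49.3	15	+	86990	786	XP_418706	na	ITB8
Frog	Xenopus tropicalis	ITB8	ITGB8	52:945,865-97,887	33.0	14	-	81104	728	XP_002933344	na	ITB8
Zebrafish	Danio rerio	ITB8	ITGB8	19:2,377,677-2,441,753	64.1	14	-	74877	669	XP_001919626	A3RI57	ITB8
Nematode	Caenorhabditis elegans	PAT3	pat3	III:3,909,309-3,914,106	4.8	8	-	90138	809	NP_497787	Q27874	OUTGROUP
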