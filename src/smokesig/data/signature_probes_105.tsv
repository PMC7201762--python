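probe_id	chromosome	gene_symbols	feature_type
cg00334821	chr7	LIMK1	OpenSea
cg00370022	chr15	CYP1A1	N_Shelf
cg00688979	chr6	CCHCR1	OpenSea
cg00702638	chr3	KIAA1143;KIF15	Island
cg00976097	chr5	AHRR	Island
cg00993400	chr1	AL672294.1;ZNF692	S_Shore
cg01049916	chr10	FGFR2	OpenSea
cg01637537	chr22	FAM83F	N_Shore
cg01971034	chr1		N_Shelf
cg02050426	chr18	CDH20	Island
cg02387679	chr5	IQGAP2	Island
cg02498206	chr3	BOC	OpenSea
cg02826525	chr2	ARHGEF33;RP11-173C1.1	Island
cg02988118	chr2		N_Shelf
cg03078488	chr7	IGF2BP3	N_Shore
cg03277049	chr3	LINC00886	Island
cg03642695	chr17	TEKT3	OpenSea
cg03789372	chr8		OpenSea
cg03806812	chr2		OpenSea
cg03945895	chr1	PRDM2	OpenSea
cg03985801	chr1	LGR6	N_Shore
cg04267214	chr1		Island
cg04616529	chr16	CLEC16A	OpenSea
cg04865290	chr3	TMEM110;TMEM110-MUSTN1	N_Shelf
cg05033369	chr1	FCRLA	OpenSea
cg05559381	chr5		OpenSea
cg05575921	chr5	AHRR	N_Shore
cg05752786	chr1	SYT2	Island
cg05787209	chr16	STX1B	S_Shore
cg05951221	chr2	ECEL1P1	Island
cg06010163	chr6		OpenSea
cg06227763	chr18		OpenSea
cg06540950	chr5		OpenSea
cg06637330	chr5		N_Shelf
cg07160783	chr16		OpenSea
cg07325233	chr21	AP000295.9;IL10RB;IL10RB-AS1	Island
cg07709148	chr8	RP11-486M23.1	OpenSea
cg07813142	chr2	SP5	Island
cg08008475	chr13	RNY1P1	OpenSea
cg08374798	chr20	COL9A3	N_Shore
cg08733957	chr1	GALE	N_Shore
cg08894131	chr1	GJA5	OpenSea
cg09194449	chr7	PTPRN2	Island
cg09278187	chr1	FOXJ3	OpenSea
cg09370982	chr16	RP11-20I23.1;TBC1D24	S_Shore
cg09799983	chr2	CYP1B1;CYP1B1-AS1	Island
cg10076730	chr13	COL4A2	N_Shore
cg10354195	chr10	LRRC27	OpenSea
cg10385390	chr1	PARK7	S_Shore
cg10413224	chr7	BMPER	Island
cg10650290	chr7	PTPRN2	OpenSea
cg11545521	chr11	PTPRJ	OpenSea
cg11751707	chr2	CYP1B1;CYP1B1-AS1	Island
cg11954332	chr1	PRRX1	OpenSea
cg12020590	chr11		OpenSea
cg12387247	chr19	FCER2	OpenSea
cg13563863	chr19	FZR1	Island
cg13654445	chr9	NTRK2	OpenSea
cg13990746	chr1	ANKRD45	Island
cg14270346	chr9	RP11-613M10.9;SHB	OpenSea
cg14320852	chr9		OpenSea
cg14373988	chr1	PEX10	N_Shore
cg14419740	chr7	PTPRN2	Island
cg15233380	chr13	SHISA2	OpenSea
cg15513657	chr14	MEG3	OpenSea
cg15585555	chr1	RASSF5	S_Shore
cg15680620	chr1	ANKRD45	S_Shore
cg15922705	chr6	COL9A1	N_Shore
cg16315376	chr1	SYT2	Island
cg16322479	chr5	EXOC3;EXOC3-AS1	S_Shore
cg16377959	chr5	LINC01019	OpenSea
cg16840978	chr8	RAB11FIP1	N_Shelf
cg16884847	chr2	PRKCE	OpenSea
cg17211612	chr12	DNAH10	OpenSea
cg17373442	chr3	CHST2	Island
cg17676618	chr10		OpenSea
cg18001059	chr7	MRPL32;PSMA2	Island
cg18713316	chr1	KCNN3	Island
cg18883807	chr14		OpenSea
cg18919659	chr22	PACSIN2	OpenSea
cg19341901	chr7		OpenSea
cg19859270	chr3	CPOX;GPR15	OpenSea
cg20439473	chr17	VEZF1	N_Shelf
cg20459495	chr2		OpenSea
cg20538211	chr4	IGFBP7-AS1	N_Shelf
cg20546279	chr7		S_Shore
cg20628376	chr10	RP11-351M16.3	OpenSea
cg21012061	chr1	ELK4;MFSD4	OpenSea
cg21083936	chr11		S_Shelf
cg21500300	chr12	BCAT1;RP11-662I13.2	S_Shore
cg21885107	chr14	PAPLN;RP4-647C14.2	Island
cg23369748	chr6	SASH1	OpenSea
cg23501962	chr11	RP4-683L5.1;SLC1A2	N_Shore
cg23854567	chr12	PXN	OpenSea
cg24203542	chr11	NAV2	OpenSea
cg24279017	chr12	ETV6	OpenSea
cg24772753	chr2	SP5	Island
cg25192619	chr6	CCDC167	Island
cg26005485	chr8	FAM135B	N_Shore
cg26029292	chr8	ZNF7	S_Shelf
cg26076054	chr5	AHRR	Island
cg26582784	chr7	AC002454.1;CDK6	Island
cg26799398	chr1	ECM1;TARS2	OpenSea
cg26972614	chr11	IL18BP	OpenSea
cg27052537	chr7		OpenSea
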