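# Amplicon config transcribed from the study's 48-target multiplex bisulfite PCR panel (hg38).
# Coordinates are 0-based half-open; primer lengths are the locus-specific primer lengths
# (printed primer minus the 33/34 nt Illumina Nextera adapter tail).
# PLACEHOLDER SPANS: the source table gives only a chromosome (or no location) for these rows;
# their start/end below are documented placeholders, not genomic coordinates:
#   AluSx_1, AluSx_2, L1ME_ORF2_1, L1ME_ORF2_2, foxe3_1, foxe3_2, foxp3_1, foxp3_2, tlx3_1, tlx3_2, uniq_noCG_1, uniq_noCG_2, mgmt_1, mgmt_2, mito_1, mito_2
# chrom	start	end	name	fwd_primer_len	rev_primer_len
chr4	154710459	154710544	mandatory01	26	23
chr1	110052408	110052486	mandatory02	23	27
chr4	7526638	7526703	mandatory03	30	27
chr2	164593224	164593299	mandatory04	26	26
chr2	9518295	9518358	mandatory05	30	28
chr17	80709099	80709203	mandatory06	25	22
chr3	142837968	142838050	mandatory07	25	28
chr7	140218099	140218192	mandatory08	27	25
chr7	26206541	26206614	mandatory09	31	27
chr7	3025553	3025664	mandatory10	24	26
chr7	138229945	138230021	mandatory11	34	28
chr2	42275713	42275789	mandatory12	23	27
chr15	100249154	100249220	mandatory13	27	27
chr4	147557820	147557938	mandatory14	29	27
chr17	75369173	75369252	mandatory15	22	25
chr7	93520243	93520332	mandatory16	31	24
chr11	2017872	2018050	h19	33	30
chr7	130131097	130131299	mest	31	28
chrX	73070974	73071183	xist	33	29
chr1	25256021	25256153	runx3	24	21
chr3	25469821	25469959	rarb	28	28
chr3	37034572	37034734	mlh1	23	30
chr3	50378199	50378398	rassf1a	29	25
chr5	112073446	112073596	apc	22	25
chr9	21974959	21975097	cdkn2a	29	26
chr9	90112782	90112938	dapk1_p1	23	30
chr9	90112990	90113144	dapk1_p2	21	21
chr9	90113587	90113759	dapk1_i1	21	32
chr11	67351063	67351273	gstp1	24	26
chr16	68771005	68771197	cdh1_snp	27	31
chr16	68771200	68771385	cdh1_3p	26	28
chr17	41277329	41277493	brca1	31	30
chrUn	10000000	10000115	AluSx_1	28	27
chrUn	10100000	10100113	AluSx_2	27	26
chrUn	10200000	10200120	L1ME_ORF2_1	30	30
chrUn	10300000	10300122	L1ME_ORF2_2	30	32
chr1	10400000	10400060	foxe3_1	0	0
chr1	10500000	10500111	foxe3_2	23	28
chrX	10600000	10600110	foxp3_1	26	24
chrX	10700000	10700109	foxp3_2	23	26
chr5	10800000	10800115	tlx3_1	28	27
chr5	10900000	10900112	tlx3_2	24	28
chr5	11000000	11000120	uniq_noCG_1	27	33
chr5	11100000	11100119	uniq_noCG_2	28	31
chr10	11200000	11200108	mgmt_1	24	24
chr10	11300000	11300111	mgmt_2	23	28
chrM	11400000	11400120	mito_1	34	26
chrM	11500000	11500119	mito_2	29	30
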