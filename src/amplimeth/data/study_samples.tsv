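# Sample manifest transcribed from the study's 86-sample design.
# One row (marked PLACEHOLDER) was not recoverable from the source table text.
sample_name	description	accession
293	HEK-293 embryonic kidney cell line. ATCC CRL1573	GSE67856
40424	Normal fibroblast cell line	GSE67856
910046	Normal fibroblast cell line	GSE67856
12A-CD19	Normal Fluorescent Activated Cell Sorted (FACS) CD19 positive bone marrow cells from individual 12A	GSE67856
12A-CD33	Normal Fluorescent Activated Cell Sorted (FACS) CD33 positive bone marrow cells from individual 12A	GSE67856
12A-CD34	Normal Fluorescent Activated Cell Sorted (FACS) CD34 positive bone marrow cells from individual 12A	GSE67856
12A-CD45	Normal Fluorescent Activated Cell Sorted (FACS) CD45 positive bone marrow cells from individual 12A	GSE67856
6-MDA453	MDA-MB-453 metastatic breast cancer cell line. ATCC HTB-131	GSE67856
6C-CD19	Normal Fluorescent Activated Cell Sorted (FACS) CD19 positive bone marrow cells from individual 6C	GSE67856
6C-CD33	Normal Fluorescent Activated Cell Sorted (FACS) CD33 positive bone marrow cells from individual 6C	GSE67856
6C-CD34	Normal Fluorescent Activated Cell Sorted (FACS) CD34 positive bone marrow cells from individual 6C	GSE67856
6C-CD45	Normal Fluorescent Activated Cell Sorted (FACS) CD45 positive bone marrow cells from individual 6C	GSE67856
9A-CD19	Normal Fluorescent Activated Cell Sorted (FACS) CD19 positive bone marrow cells from individual 9A	GSE67856
9A-CD33	Normal Fluorescent Activated Cell Sorted (FACS) CD33 positive bone marrow cells from individual 9A	GSE67856
9A-CD34	Normal Fluorescent Activated Cell Sorted (FACS) CD34 positive bone marrow cells from individual 9A	GSE67856
9A-CD45	Normal Fluorescent Activated Cell Sorted (FACS) CD45 positive bone marrow cells from individual 9A	GSE67856
9A-Whole-Blood	Whole blood sample from individual 9A	GSE67856
BRL	Normal lymphoblast cell line.	GSE67856
CaCo	Caco2 Colon cancer cell line. ATCC HTB37	GSE67856
DG75	Lymphoblast cancer cell line. ATCC CRL-2625	GSE67856
EKVX	Cancer Cell Line	GSE67856
HELA	Cancer cell line. ATCC CCL-2	GSE67856
HEPG2	Liver cancer cell line. ATCC HB-8065	GSE67856
HT1080	Cancer cell line. ATCC CCL121	GSE67856
HTB22-Col	MCF7 breast cancer cell line. ATCC HTB22	GSE67856
JWL	Normal lymphoblast cell line.	GSE67856
K562	CML cancer cell line. ATCC CCL-243	GSE67856
Sample29	Cell Line	GSE71804
MB231BAG	Breast cancer cell line. ATCC HTB-26	GSE67856
MCF7	Breast cancer cell line. ATCC HTB22	GSE67856
NALM6	Leukaemia cell line. ACC 128	GSE67856
NCCIT	Embryonic carcinoma cell line. ATCC CRL-2073	GSE67856
OVCAR8	Cancer cell line	GSE67856
SKNAS	Neuroblastoma cancer cell line. ATCC CRL2137	GSE67856
U231	Cancer cell line	GSE67856
Sample1	Human normal colon tissue	GSE71804
Sample2	Human colon tumor	GSE71804
Sample3	Human normal colon tissue	GSE71804
Sample4	Human colon tumor	GSE71804
Sample5	Human normal colon tissue	GSE71804
Sample6	Human colon tumor	GSE71804
Sample7	Human normal colon tissue	GSE71804
Sample8	Human colon tumor	GSE71804
Sample9	Human normal colon tissue	GSE71804
Sample10	Human colon tumor	GSE71804
Sample11	Human normal colon tissue	GSE71804
Sample12	Human colon tumor	GSE71804
Sample13	Pooled human cancer and blood cell DNA	GSE71804
Sample14	Pooled human cancer and blood cell DNA	GSE71804
Sample15	Pooled human cancer and blood cell DNA	GSE71804
Sample16	Pooled human cancer and blood cell DNA	GSE71804
Sample17	Pooled human cancer and blood cell DNA	GSE71804
Sample18	Pooled human cancer and blood cell DNA	GSE71804
Sample19	Artificially methylated human DNA	GSE71804
Sample20	Artificially methylated human DNA	GSE71804
Sample21	Artificially methylated human DNA	GSE71804
Sample22	Artificially methylated human DNA	GSE71804
Sample23	Artificially methylated human DNA	GSE71804
Sample24	Artificially methylated human DNA	GSE71804
Sample25	Human leukemia cell line	GSE71804
Sample26	Human leukemia cell line	GSE71804
Sample27	Human leukemia cell line	GSE71804
Sample28	Human leukemia cell line	GSE71804
468-C1-3-9_S40	MDA-468 cell line, control 1	GSE71804
468-C2-3-9_S48	MDA-468 cell line, control 2	GSE71804
468-S1-3-9_S56	MDA-468 cell line + EGF 1	GSE71804
468-S2-3-9_S64	MDA-468 cell line + EGF 2	GSE71804
ET-C1-3-9_S71	PMC42-ET cell line, control 1	GSE71804
ET-C2-3-9_S79	PMC42-ET cell line, control 2	GSE71804
ET-S1-3-9_S87	PMC42-ET cell line, +EGF 1	GSE71804
ET-S2-3-9_S95	PMC42-ET cell line, +EGF 2	GSE71804
LA-C1-3-9_S8	PMC42-LA cell line, control 1	GSE71804
LA-C3-3-9_S16	PMC42-LA cell line, control 2	GSE71804
LA-S1-3-9_S24	PMC42-LA cell line, +EGF 1	GSE71804
LA-S2-3-9_S32	PMC42-LA cell line, +EGF 2	GSE71804
PMC42ET-72-C_S31	PMC42-ET cell line, control 72 h	GSE71804
PMC42ET-72h-EGF_S39	PMC42-ET cell line, +EGF 72 h	GSE71804
PMC42ET-9d-C_S47	PMC42-ET cell line, control 9 days	GSE71804
PMC42ET-9d-EGF_S55	PMC42-ET cell line, +EGF 9 days	GSE71804
PMC42ET-9d-TGFb_S63	PMC42-ET cell line, +TGFb 9 days	GSE71804
PMC42LA-72h-C_S86	PMC42-LA cell line, control 72 h	GSE71804
PMC42LA-72h-EGF_S94	PMC42-LA cell line, +EGF 72 h	GSE71804
PMC42LA-9d-C_S7	PMC42-LA cell line, control 9 days	GSE71804
PMC42LA-9d-EGF_S15	PMC42-LA cell line, +EGF 9 days	GSE71804
PMC42LA-9d-TGFb_S23	PMC42-LA cell line, +TGFb 9 days	GSE71804
unrecovered-sample-86	PLACEHOLDER: one manifest row could not be recovered from the source table text; the study design comprises 86 samples	
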