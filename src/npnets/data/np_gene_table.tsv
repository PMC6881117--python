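gene_id	role	cognate_partners	galpha_family	predicted_products	peak_fpkm	pfpkm_percentile	pfpkm_rank	pct_cells
Npy	NPP	Npy1r|Npy2r|Npy5r		Neuropeptide Y	108865	100.00	1	42
Sst	NPP	Sstr1|Sstr2|Sstr3|Sstr4		Somatostatins	70274	99.99	2	26
Vip	NPP	Vipr1|Vipr2		Vasoactive Intestinal Peptide	48747	99.99	3	33
Tac2	NPP	Tacr3		Neurokinin B	18284	99.98	4	15
Cck	NPP	Cckbr		Cholecystokinins	16396	99.97	6	69
Penk	NPP	Oprd1|Oprm1		Enkephalins	11160	99.96	8	26
Crh	NPP	Crhr1|Crhr2		Corticotropin-Releasing Hormone	9118	99.95	10	17
Cort	NPP	Sstr1|Sstr2|Sstr3|Sstr4		Cortistatin	7477	99.93	15	32
Tac1	NPP	Tacr1		Substance P, Neurokinin A	5728	99.92	18	11
Pdyn	NPP	Oprd1|Oprk1|Oprm1		Dynorphins	2813	99.69	68	8
Pthlh	NPP	Pth1r		Parathyroid-Hormone-Like Hormone	1656	99.29	156	18
Pnoc	NPP	Oprl1		Nociceptins	698	97.68	509	23
Trh	NPP	Trhr|Trhr2		Thyrotropin-Releasing Hormone	510	96.51	766	3
Grp	NPP	Grpr		Gastrin-Releasing Peptide	435	95.59	968	12
Rln1	NPP	Rxfp1|Rxfp2|Rxfp3		Relaxin 1	258	91.99	1757	7
Adcyap1	NPP	Adcyap1r1|Vipr1|Vipr2		Adenylate Cyclase-Activating Polypeptides	165	87.29	2788	26
Nts	NPP	Ntsr1|Ntsr2		Neurotensin	121	82.14	3917	1
Nmb	NPP	Nmbr		Neuromedin B	112	80.53	4270	14
Sstr2	NP-GPCR	Sst|Cort	Gi/o	Somatostatin Receptor 2	413	95.3		42
Npy2r	NP-GPCR	Npy	Gi/o	Neuropeptide Y Receptor Y2	291	93.1		10
Npy1r	NP-GPCR	Npy	Gi/o	Neuropeptide Y Receptor Y1	272	92.4		50
Grpr	NP-GPCR	Grp	Gq/11	GRP Receptor	231	91		10
Cckbr	NP-GPCR	Cck	Gq/11	Cholecystokinin B Receptor	210	90		52
Ntsr2	NP-GPCR	Nts	Gq/11	Neurotensin Receptor 2	161	86.9		17
Npy5r	NP-GPCR	Npy	Gi/o	Neuropeptide Y Receptor Y5	152	86.1		28
Nmbr	NP-GPCR	Nmb	Gq/11	Neuromedin B Receptor	123	82.4		8
Rxfp1	NP-GPCR	Rln1	Gs	Relaxin Family Receptor 1	121	82		22
Sstr4	NP-GPCR	Sst|Cort	Gi/o	Somatostatin Receptor 4	106	79.5		28
Trhr	NP-GPCR	Trh	Gq/11	TRH Receptor	101	78.4		3
Sstr1	NP-GPCR	Sst|Cort	Gi/o	Somatostatin Receptor 1	90	76		38
Adcyap1r1	NP-GPCR	Adcyap1	Gs	ADCYAP1 Receptor 1	89	75.8		71
Crhr1	NP-GPCR	Crh	Gs	CRH Receptor 1	86	74.9		28
Rxfp3	NP-GPCR	Rln1	Gi/o	Relaxin Family Receptor 3	85	74.7		5
Oprl1	NP-GPCR	Pnoc	Gi/o	Opioid Receptor-Like 1	82	73.8		48
Crhr2	NP-GPCR	Crh	Gs	CRH Receptor 2	72	70.7		3
Tacr3	NP-GPCR	Tac2	Gq/11	Tachykinin Receptor 3	65	68		3
Oprk1	NP-GPCR	Pdyn	Gi/o	Kappa-Opioid Receptor	64	67.4		3
Tacr1	NP-GPCR	Tac1	Gq/11	Tachykinin Receptor 1	56	64.2		3
Pth1r	NP-GPCR	Pthlh	Gq/11	PTH 1 Receptor	51	61.6		15
Vipr1	NP-GPCR	Vip|Adcyap1	Gs	VIP Receptor 1	41	56.1		28
Oprm1	NP-GPCR	Penk|Pdyn	Gi/o	Mu-Opioid Receptor	35	52.1		43
Trhr2	NP-GPCR	Trh	Gq/11	TRH Receptor 2	30	48.9		10
Vipr2	NP-GPCR	Vip|Adcyap1	Gs	VIP Receptor 2	30	48.4		0.5
Rxfp2	NP-GPCR	Rln1	Gs	Relaxin Family Receptor 2	28	47.3		4
Oprd1	NP-GPCR	Penk|Pdyn	Gi/o	Delta-Opioid Receptor	26	45.8		13
Ntsr1	NP-GPCR	Nts	Gq/11	Neurotensin Receptor 1	24	44.3		10
Sstr3	NP-GPCR	Sst|Cort	Gi/o	Somatostatin Receptor 3	17	39.5		21
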