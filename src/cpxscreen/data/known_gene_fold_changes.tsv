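# Average qRT-PCR fold differences in expression for previously reported
# CpxR-regulated genes, relative to wild-type BW25113 (positive-control panel).
# Conditions as in screen_fold_changes.tsv; empty cells mean <2-fold.
gene	cpxA24	dcpxA	pnlpE	dcpxR_pnlpE
degP	26.60	2.91	32.41	6.43
htpX	25.23	17.94	37.59	0.61
cpxP	18.99	7.59	60.27	0.03
ftnB	2.05	1.39	3.24	0.49
sbmA	5.75	0.94	3.20	1.69
srkA	3.49	1.40	0.90	1.81
tsr	5.01	2.06	0.79	1.09
yccA	3.96	3.62	4.89	0.03
slt	6.57	3.32	5.07	0.31
alx	5.36	3.55	4.61	2.06
ompC	1.23	0.82	1.16	0.02
efeU	0.53	0.52	0.02	2.61
amiC	1.53	0.83	0.87	0.84
psd	8.46	2.58	2.03	0.71
motA			0.44	1.38
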