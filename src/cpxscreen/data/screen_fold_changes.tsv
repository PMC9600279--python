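# Average qRT-PCR fold differences in expression for the 73 newly identified
# CpxR-regulated genes of the genome-wide screen, relative to wild-type BW25113.
# Conditions: cpxA24 (constitutively active allele), dcpxA (cpxA deletion),
# pnlpE (NlpE overexpression), dcpxR_pnlpE (NlpE overexpression in a cpxR deletion).
# Empty cells mean an insignificant (<2-fold) difference was measured.
gene	cpxA24	dcpxA	pnlpE	dcpxR_pnlpE
carA	42.76	1.16	5.70	0.42
carB	31.80	3.02	34.10	5.20
glsA	0.08	0.29	0.01	0.13
metC	0.40	0.22	0.08	0.06
edd	2.26	0.61	0.77	0.44
astC			0.13	0.25
epmB	2.43	1.78	0.48	0.53
yhdW	0.12	0.25	0.29	2.18
sdaC			0.31	0.28
fdnG	7.34	1.41	0.59	3.01
hcp	2.37	1.70	0.15	1.03
appC	0.18	0.17	0.16	0.28
atpI	3.42	1.25	2.88	1.19
cyoA			0.32	0.29
frc			6.18	1.26
atpB	4.95	3.51	0.51	0.3
nrfA	10.25	3.57
chaA	44.89	13.10	5.37	0.57
chaB	0.21	0.22	0.26	1.90
copA	2.06	1.21
fetA	0.23	0.26	0.30	0.29
xylE			0.80	3.59
focA			0.72	0.06
ybaL			0.25	1.04
gudP	0.42	1.91
ydeE	0.38	0.50	0.28	1.36
araF	1.13	0.27
yddG	2.39	1.38	0.42	0.98
eamA	0.44	0.58	0.27	0.78
gpmM	4.92	0.82	0.15	0.03
frmB			0.46	0.75
gapC			0.17	0.06
gmhA			0.26	0.46
galP			0.58	3.58
ascF			0.47	0.84
btsT			0.06	1.01
ylaB	0.42	0.53	0.37	0.98
bluR	0.25	0.40	0.25	0.26
fis	3.98	2.07
ettA	2.43	1.76	0.50	0.28
cspA			0.86	0.33
prlF			0.25	0.33
cbl			11.85	98.39
ecpR			0.90	6.44
feaR			0.36	1.14
exbB			0.70	0.20
ampH	3.45	2.58	2.21	0.72
casA	4.16	1.06	3.76	0.83
shoB	0.37	0.60	0.09	3.28
inaA			3.38	1.26
qmcA	0.21	0.43	0.21	1.26
dgkA	2.02	1.46
fadI	3.94	1.78	0.43	0.79
fadE	12.02	3.35	0.24	2.63
acs	0.97	7.28	0.11	2.55
plsB			0.89	2.42
gstA			0.71	0.26
dsbG			0.27	0.14
ohsC	0.35	0.73
xthA	2.52	1.20	0.47	0.58
dusB	4.35	1.80
rhlB			0.75	0.47
fimB	0.12	0.15	0.09	0.13
mtn			0.91	0.40
dgt			0.77	0.29
yhdU	2.52	1.34	2.24	2.43
yncD	1.36	2.09
yncE	4.09	1.18	0.27	0.09
yfaH			1.08	7.71
yhdJ			1.09	2.86
ygjR			0.37	0.11
yibN			0.55	0.20
yacH			3.87	0.90
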