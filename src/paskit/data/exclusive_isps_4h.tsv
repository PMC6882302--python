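procedure	pathway	pas
ALPPS	IGF1R signaling pathway (cell survival)	0.09677963
ALPPS	ILK pathway (induced cell proliferation)	0.18650255
ALPPS	IL-10 pathway (stability determination)	1.84821924
ALPPS	Interferon pathway (transcription)	-0.47974021
PVL	AKT pathway (cell cycle)	0.09431465
PVL	Androgen receptor pathway (cell survival and cell growth)	0.1243162
PVL	ATM pathway (cell survival)	0.05295231
PVL	cAMP main pathway	0.05587309
PVL	cAMP pathway (degradation of cell cycle regulators)	-0.04355851
PVL	Erythropoeitin main pathway	0.04643793
PVL	Hedgehog pathway (repression of Hh, BMP)	0.08050423
PVL	HGF Pathway (Anoikis)	0.20617418
PVL	HIF1-Alpha main pathway	0.06045947
PVL	HIF1Alpha pathway (gene expression)	0.14085828
PVL	HIF1Alpha pathway (NOS pathway)	0.16252878
PVL	HIF1Alpha pathway (Pyruvate)	0.14085828
PVL	HIF1Alpha pathway (VEGF pathway)	0.13205464
PVL	IL-10 main pathway	0.27795708
PVL	lntegrin signaling pathway (cytoskeleton contraction integrin modulation cell invasion and migration)	0.12105071
PVL	Interferon main pathway	0.03386061
PVL	IP3 main pathway	0.03666389
PVL	MAPK family pathway (gene Expression)	0.03057693
PVL	RAS main pathway	0.04229486
PVL	TGF beta pathway (post-transcriptional G1 arrest)	0.13784324
transection	Glucocorticoid receptor pathway (gene expression)	-0.01557421
transection	Growth hormone pathway (gene expression)	0.02746121
transection	IL-2 pathway (actin reorganization)	0.4806433
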