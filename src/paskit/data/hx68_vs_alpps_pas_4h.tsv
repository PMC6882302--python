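pathway	pas_hx68	pas_alpps
Androgen receptor pathway (gonadotropin regulation)	0.080962033	0.170591759
Androgen receptor pathway (histone modification)	0.080962033	0.170591759
Androgen receptor pathway (prostate differentiation and development)	0.080962033	0.170591759
Androgen receptor pathway (sexual differentiation and sexual maturation at puberty)	0.080962033	0.170591759
ATM main pathway	0.069585724	0.164331506
ATM pathway (G2_M checkpoint arrest)	0.192334187	0.758265977
BRCA 1 main pathway	-0.01618013	-0.173732307
EGFR main pathway	0.062796782	0.101805817
ErbB family main pathway	0.05751811	0.172579526
GPCR pathway (gene expression)	0.068563364	0.123092979
HGF main pathway	0.062203501	0.112692194
HGF pathway (cell cycle progression)	0.337396472	0.546430817
Hypoxia pathway EMT 1	0.084001749	0.691549538
Hypoxia pathway EMT 2	0.084001749	0.691549538
Hypoxia pathway EMT 3	0.084001749	0.691549538
Hypoxia pathway EMT 4	0.084001749	0.691549538
ILK Main Pathway	0.074326641	0.17275502
ILK Pathway (Apoptosis)	0.091947966	0.169660241
ILK Pathway (Cell adhesion, cell motility, opsonization)	0.095965334	0.218655438
ILK pathway (cell cycle proliferation)	0.08622972	0.180086957
ILK pathway (cell migration, retraction)	0.094442075	0.206157845
ILK pathway (cell motility)	0.080839955	0.19368415
ILK pathway (cytoskeletal reorganization)	0.115000716	0.249836663
ILK pathway (G2-phase arrest)	0.08622972	0.180086957
ILK pathway (induced cell proliferation)	0.197724934	0.186502548
ILK pathway (regulation of intermediate filaments)	0.106090655	0.23979623
ILK pathway (regulation of junction assembly of desmosomes)	0.095197611	0.216906194
ILK pathway (wound healing)	0.095197611	0.224489964
IL-10 pathway (stability determination)	0.053478054	1.848219244
IL-2 main pathway	0.017026437	0.113993181
lntegrin signaling main pathway	0.067439974	0.145964253
JNK pathway (apoptosis, inflammation, tumorigenesis, cell migration)	0.079482132	0.207123801
JNK pathway (insulin signaling)	-0.07241052	-0.426061537
MAPK signaling main pathway	0.0519986	0.108187021
MAPK signaling pathway (cell survival, inflammation, apoptosis, osmoregulation)	0.212081896	0.229612073
MAPK signaling pathway (gene expression)	0.091194477	0.149905425
mTOR pathway (actin organization)	0.059587334	0.128667337
p53 signaling (negative) main pathway	0.084470457	0.14626007
PAK main pathway	0.034655373	0.117954615
SMAD (negative) main pathway	0.139663741	0.315152085
SMAD (positive) main pathway	0.139663741	0.315152085
TGF beta pathway (SnON degradation)	0.166857414	0.576950547
TGF beta pathway (tumorigenesis)	0.238367734	0.512365322
TGF beta pathway (tumor suppression)	0.238367734	0.512365322
TNF (positive) pathway (gene expression, cell survival)	0.157317821	0.326862624
VEGF pathway (actin reorganization)	0.114882119	0.070794654
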