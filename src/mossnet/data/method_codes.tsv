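raw	code
Not Reported	NR
Affinity Capture	AC
Affinity Capture-MS	AC
Affinity Capture-Western	AC
Affinity Capture-RNA	AC
Affinity Capture-Luminescence	AC
Negative Genetic	NG
Two-hybrid	Y2H
Yeast Two Hybrid	Y2H
Yeast-two-hybrid	Y2H
two hybrid	Y2H
Phenotypic Enhancement	PE
Synthetic Lethality	SL
Synthetic Growth Defect	SGD
Dosage Rescue	DR
Phenotypic Suppression	PS
Positive Genetic	PG
Reconstituted Complex	RC
Co-purification	Co-P
Copurification	Co-P
Synthetic Rescue	SR
Biochemical Activity	BA
Protein-peptide	Prot
Protein/Peptide	Prot
Co-fractionation	Co-F
Cofractionation	Co-F
Co-crystal Structure	Co-CS
Co-localization	Co-L
Colocalization	Co-L
Dosage Lethality	DL
Far Western	FW
Synthetic Haploinsufficiency	SH
Dosage Growth Defect	DGD
FRET	FRET
fluorescence resonance energy transfer	FRET
PCA	PCA
protein complementation assay	PCA
NR	NR
AC	AC
NG	NG
Y2H	Y2H
PE	PE
SL	SL
SGD	SGD
DR	DR
PS	PS
PG	PG
RC	RC
Co-P	Co-P
SR	SR
BA	BA
Co-F	Co-F
Co-CS	Co-CS
Co-L	Co-L
DL	DL
FW	FW
SH	SH
DGD	DGD
Prot	Prot
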