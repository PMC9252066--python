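# Default cis-regulatory element catalog (PlantCARE-style consensi, IUPAC alphabet).
# Consensus strings are editable configuration transcribed from commonly cited
# PlantCARE entries; verify against the live PlantCARE database before relying on
# absolute counts — element *names* and categories are the stable part.
name	consensus	category
ABRE	ACGTG	phytohormone
CGTCA-motif	CGTCA	phytohormone
ERE	ATTTTAAA	phytohormone
GARE-motif	TCTGTTG	phytohormone
P-box	CCTTTTG	phytohormone
TGA-element	AACGAC	phytohormone
TCA-element	CCATCTTTTT	phytohormone
AuxRR-core	GGTCCAT	phytohormone
ARE	AAACCA	abiotic/biotic
LTR	CCGAAA	abiotic/biotic
MBS	CAACTG	abiotic/biotic
TC-rich	GTTTTCTTAC	abiotic/biotic
MRE	AACCTAA	abiotic/biotic
Box 4	ATTAAT	abiotic/biotic
G-box	CACGTG	abiotic/biotic
I-box	GATAAG	abiotic/biotic
WUN-motif	AAATTTCCT	abiotic/biotic
CAT-box	GCCACT	development/metabolism
CCGTCC	CCGTCC	development/metabolism
O2-site	GATGAYRTGR	development/metabolism
HD-Zip 1	CAATWATTG	development/metabolism
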