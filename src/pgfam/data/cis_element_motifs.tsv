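# Promoter cis-element dictionary: name, functional category, IUPAC consensus.
# Consensus strings follow common PlantCARE-style literature conventions; the
# dictionary is data, not code — swap in your own export to mirror a specific
# database version.
name	category	consensus
CGTCA-motif	hormone	CGTCA
TGACG-motif	hormone	TGACG
ABRE	hormone	ACGTG
TCA-element	hormone	CCATCTTTTT
GARE-motif	hormone	TCTGTTG
P-box	hormone	CCTTTTG
TATC-box	hormone	TATCCCA
TGA-box	hormone	TGACGTAA
AuxRR-core	hormone	GGTCCAT
LTR	abiotic_stress	CCGAAA
MBS	abiotic_stress	CAACTG
ARE	abiotic_stress	AAACCA
WUN-motif	abiotic_stress	AAATTTCCT
G-box	light	CACGTG
Box-4	light	ATTAAT
GT1-motif	light	GGTTAA
CCAAT-box	development	CAACGG
O2-site	development	GATGAYRTGR
RY-element	development	CATGCA
motif-I	development	AACGGTT
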