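gene	description	human_orthologs
HTA2	Histone H2A	H2A
NUP170	Subunit of inner ring of nuclear pore complex	NUP155
CSM1	Nucleolar protein that mediates homolog segregation during meiosis I
YDL162C	Dubious open reading frame; overlaps the CDC9 promoter	LIG1
MSH6	Protein required for mismatch repair in mitosis and meiosis	MSH6
CHL4	Outer kinetochore protein required for chromosome stability	CENPN
RNH202	Ribonuclease H2 subunit	RNASEH2B
RAD4	Protein that recognizes and binds damaged DNA during NER	XPC
YER188W	Putative protein of unknown function
DST1	General transcription elongation factor TFIIS	TCEA1,TCEA2,TCEA3
RAD6	Ubiquitin-conjugating enzyme	UBE2A,UBE2B
RRM3	DNA helicase involved in rDNA replication and Ty1 transposition	PIF1
THP2	Subunit of the THO and TREX complexes
SKN7	Nuclear response regulator and transcription factor	HSF1,HSF2,HSF4,HSF5
HYR1	Thiol peroxidase	GPX1,GPX2,GPX3,GPX4,GPX5,GPX6,GPX7
RAD27	5' to 3' exonuclease, 5' flap endonuclease	FEN1
APN1	Major apurinic/apyrimidinic endonuclease	APE1
RNH203	Ribonuclease H2 subunit	RNASEH2C
TOP3	DNA Topoisomerase III	TOP3A
YLR235C	Dubious open reading frame; overlaps the TOP3 gene	TOP3A
YAP1	Basic leucine zipper transcription factor
TSA1	Thioredoxin peroxidase	PRDX1,PRDX2,PRDX3,PRDX4
CSM3	Replication fork associated factor	TIPIN
MLH1	Protein required for mismatch repair in mitosis and meiosis	MLH1
SGS1	RecQ family nucleolar DNA helicase	BLM
ABZ2	Aminodeoxychorismate lyase (4-amino-4-deoxychorismate lyase)
RNH201	Ribonuclease H2 catalytic subunit	RNASEH2A
PMS1	ATP-binding protein required for mismatch repair	PMS1
MGS1	Protein with DNA-dependent ATPase and ssDNA annealing activities	WRNIP1
TOF1	Subunit of a replication-pausing checkpoint complex	TIMELESS
MSH2	Protein that binds to DNA mismatches	MSH2
DFG16	Probable multiple transmembrane protein
ELG1	Subunit of an alternative replication factor C complex	ATAD5
RMI1	Subunit of the RecQ (Sgs1) - Topo III (Top3) complex	RMI1
VMA11	Vacuolar ATPase V0 domain subunit c'	ATP6VOC
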