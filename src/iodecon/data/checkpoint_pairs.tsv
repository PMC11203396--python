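ligand	receptor	interaction_class	annotation	source_set
CD274	PDCD1	inhibitory	PD-L1 on tumor/APC to PD-1 on T cells	checkpoint
PDCD1LG2	PDCD1	inhibitory	PD-L2 on APC to PD-1 on T cells	checkpoint
CD80	CTLA4	inhibitory	B7-1 on APC to CTLA-4 on T cells	checkpoint
CD86	CTLA4	inhibitory	B7-2 on APC to CTLA-4 on T cells	checkpoint
CD80	CD28	activating	B7-1 costimulation of T cells	checkpoint
CD86	CD28	activating	B7-2 costimulation of T cells	checkpoint
ICOSLG	ICOS	activating	ICOS-L on APC to ICOS on T cells	checkpoint
TNFSF4	TNFRSF4	activating	OX40L to OX40	checkpoint
TNFSF9	TNFRSF9	activating	4-1BBL to 4-1BB	checkpoint
TNFSF14	TNFRSF14	activating	LIGHT to HVEM	checkpoint
TNFSF18	TNFRSF18	activating	GITRL to GITR	checkpoint
CD70	CD27	activating	CD70 on APC to CD27 on T/NK cells	checkpoint
CD40LG	CD40	activating	CD40L on T cells to CD40 on APC	checkpoint
HLA-E	KLRC1	inhibitory	HLA-E to NKG2A on NK/T cells	checkpoint
LGALS9	HAVCR2	inhibitory	Galectin-9 to TIM-3	checkpoint
NECTIN2	TIGIT	inhibitory	CD112 to TIGIT	checkpoint
PVR	TIGIT	inhibitory	CD155 to TIGIT	checkpoint
CEACAM1	HAVCR2	inhibitory	CEACAM1 to TIM-3	checkpoint
HLA-DRA	LAG3	inhibitory	MHC class II to LAG-3	checkpoint
BTLA	TNFRSF14	inhibitory	BTLA to HVEM	checkpoint
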