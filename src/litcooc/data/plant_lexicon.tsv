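# Demonstration lexicon: plant proteins/genes, trigger terms, concepts, taxa.
# Columns are tab-separated; first column is the row type.
BIOENTITY	rbcL	rbcL	protein
BIOENTITY	psbA	psbA	protein
BIOENTITY	matK	matK	protein
BIOENTITY	PR-1	PR-1	protein
BIOENTITY	NPR1	NPR1	protein
BIOENTITY	PDF1.2	PDF1.2	protein
BIOENTITY	glutathione S-transferase	glutathione S-transferase	protein
BIOENTITY	GST	GST	protein
BIOENTITY	PhoB	PhoB	protein
BIOENTITY	PhoR	PhoR	protein
BIOENTITY	ERF1	ERF1	protein
BIOENTITY	MYC2	MYC2	protein
BIOENTITY	EIN2	EIN2	protein
BIOENTITY	JAR1	JAR1	protein
BIOENTITY	COI1	COI1	protein
BIOENTITY	WRKY33	WRKY33	gene
BIOENTITY	PAL1	PAL1	gene
BIOENTITY	ICS1	ICS1	gene
BIOENTITY	LOX2	LOX2	gene
BIOENTITY	ACS6	ACS6	gene
BIOENTITY	leaf epidermis	leaf epidermis	tissue
BIOENTITY	root cortex	root cortex	tissue
BIOENTITY	mesophyll cell	mesophyll cell	cell_type
BIOENTITY	guard cell	guard cell	cell_type
TERM	activates
TERM	binds
TERM	interacts
TERM	inhibits
TERM	induces
TERM	induced
TERM	encoding
TERM	encode
TERM	amplified
TERM	regulates
TERM	represses
TERM	phosphorylates
TERM	suppresses
TERM	stimulates
TERM	mediates
TERM	modulates
TERM	enhances
TERM	promotes
TERM	degrades
TERM	cleaves
TERM	stabilizes
TERM	transcribes
TERM	associates
TERM	targets
TERM	upregulates
TERM	downregulates
TERM	catalyzes
TERM	acetylates
TERM	methylates
TERM	ubiquitinates
TERM	silences
TERM	triggers
TERM	antagonizes
TERM	sequesters
TERM	recruits
TERM	dimerizes
TERM	accumulates
TERM	transports
TERM	oxidizes
TERM	deactivates
CONCEPT	defense response
CONCEPT	cell wall
CONCEPT	photosynthesis
CONCEPT	biotic stress
CONCEPT	signal transduction
CONCEPT	chloroplast
CONCEPT	pathogen resistance
CONCEPT	jasmonic acid
CONCEPT	salicylic acid
CONCEPT	systemic acquired resistance
TAXON	Arabidopsis thaliana	3702
TAXON	Zea mays	4577
TAXON	Brachypodium distachyon	15368
TAXON	Nicotiana tabacum	4097
TAXON	Solanum tuberosum	4113
TAXON	Solanum lycopersicum	4081
TAXON	Glycine max	3847
TAXON	soybean	3847
TAXON	Phaseolus vulgaris	3885
TAXON	Lotus japonicus	34305
TAXON	Cicer arietinum	3827
TAXON	Manihot esculenta	3983
TAXON	Selaginella moellendorffii	88036
TAXON	Medicago truncatula	3880
TAXON	Nicotiana benthamiana	4100
TAXON	Ricinus communis	3988
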