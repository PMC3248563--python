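gene	functional_class	molecular_function
cdk-1	cell cycle/DNA	Cell cycle
fbxb-11	cell cycle/DNA	DNA recombination
fbxb-17	cell cycle/DNA	DNA recombination
F46F11.9	cell cycle/DNA	Meiosis
mcm-2	cell cycle/DNA	Replication
rnr-2	cell cycle/DNA	Replication
rpa-1	cell cycle/DNA	Replication
ruvb-1	cell cycle/DNA	Replication
ppn-1	cell structure/transport	Cellular matrix, cuticle
col-61	cell structure/transport	Cellular matrix, cuticle
col-69	cell structure/transport	Cellular matrix, cuticle
viln-1	cell structure/transport	Cellular matrix, cuticle
klp-15	cell structure/transport	Vesicle trafficking
nex-1	cell structure/transport	Vesicle trafficking
C50D2.2	energy/metabolism	Metabolism
R03D7.1	energy/metabolism	Metabolism
C47F8.4	energy/metabolism	Metabolism
C54C8.5	energy/metabolism	Metabolism
D2030.1	energy/metabolism	Metabolism
elo-2	energy/metabolism	Metabolism
W06H3.3	energy/metabolism	Metabolism
F43G9.1	energy/metabolism	Metabolism
T22B11.5	energy/metabolism	Metabolism
C34B2.8	energy/metabolism	Electron transport chain
F59C6.5	energy/metabolism	Electron transport chain
ucr-2.3	energy/metabolism	Electron transport chain
cyp-13B2	energy/metabolism	Electron transport chain
cyp-33D1	energy/metabolism	Electron transport chain
B0281.5	energy/metabolism	Ion transport
catp-4	energy/metabolism	Ion transport
F43E2.7	energy/metabolism	Mitochondrial function
F08H9.3	protein folding/transport	Chaperone
cyn-11	protein folding/transport	Chaperone
cyn-12	protein folding/transport	Chaperone
C30C11.4	protein folding/transport	Chaperone
dnj-22	protein folding/transport	Chaperone
phb-2	protein folding/transport	Chaperone
tag-335	protein folding/transport	Protein glycosylation
C26E6.6	protein synthesis	Mitochondrial ribosome
F33D4.5	protein synthesis	Mitochondrial ribosome
mrpl-41	protein synthesis	Mitochondrial ribosome
rpl-2	protein synthesis	Ribosomal protein
rpl-35	protein synthesis	Ribosomal protein
rps-21	protein synthesis	Ribosomal protein
krs-1	protein synthesis	Translation
F17C11.9	protein synthesis	Translation
H19N07.1	protein synthesis	Translation
R05D11.4	protein synthesis	Translation
hmg-3	RNA synthesis/processing	Nucleosome binding
hmg-4	RNA synthesis/processing	Nucleosome binding
C15H11.9	RNA synthesis/processing	Ribosome biogenesis
F13H8.2	RNA synthesis/processing	RNA processing, splicing
fib-1	RNA synthesis/processing	RNA processing, splicing
let-716	RNA synthesis/processing	RNA processing, splicing
ZK430.7	RNA synthesis/processing	RNA processing, splicing
Y110A7A.8	RNA synthesis/processing	RNA processing, splicing
C55A6.9	RNA synthesis/processing	Transcription
K03F8.1	RNA synthesis/processing	Transcription
fkh-6	RNA synthesis/processing	Transcription
gei-11	RNA synthesis/processing	Transcription
let-607	RNA synthesis/processing	Transcription
dao-5	signaling	Receptor protein
xpo-1	signaling	Receptor protein
sri-57	signaling	Receptor protein
sri-78	signaling	Receptor protein
srz-53	signaling	Receptor protein
T11F1.6	signaling	Receptor protein
clec-19	signaling	Transduction
pdl-1	signaling	Transduction
rgl-1	signaling	Transduction
W03B1.9	signaling	Transduction
C23G10.10	unknown	Unknown
C45G3.4	unknown	Unknown
F14B8.2	unknown	Unknown
F26E4.2	unknown	Unknown
F47F2.3	unknown	Unknown
K02E7.11	unknown	Unknown
ptr-19	unknown	Unknown
R05D7.2	unknown	Unknown
ril-1	unknown	Unknown
smu-1	unknown	Unknown
T04D3.5	unknown	Unknown
vab-19	unknown	Unknown
F53F10.1	unknown	Unknown
W03B1.5	unknown	Unknown
Y51H7BR.3	unknown	Unknown
fbxa-76	unknown	Unknown
F54C4.3	unknown	Unknown
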