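gene	class_code	functional_class	molecular_function	human_ortholog	ts_rescued	ts_tested
ucr-2.3	EM	energy/metabolism	Ubiquinol cytochrome c reductase, complex III ETC	UQCRC2	3	4
F43G9.1	EM	energy/metabolism	Isocitrate dehydrogenase alpha-subunit, TCA cycle	IDH3A	2	4
T22B11.5	EM	energy/metabolism	2-oxoglutarate dehydrogenase E1 subunit, TCA cycle	OGDHL	4	4
ZK430.7	RSP	RNA synthesis/processing	Sof1-like rRNA processing protein	WDSOF1	4	4
Y110A7A.8	RSP	RNA synthesis/processing	Putative mRNA splicing factor PRP31	PRPF31	4	4
gei-11	RSP	RNA synthesis/processing	GEX-interacting protein 11, MYB family	SNAPC4	4	4
let-607	RSP	RNA synthesis/processing	CREB-ATF transcription factor	CREB3L3	4	4
R05D11.4	PS	protein synthesis	ATP-dependent RNA helicase, translation	DDX52	1	4
C45G3.4	U	unknown	Unknown	Unknown	1	4
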