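gene	accession	description	sites
ARC40	P38328	Actin-related protein 2/3 complex subunit 1	mK121
ATP2	P00830	ATP synthase subunit beta, mitochondrial precursor	mK196
CDC11	P32458	Cell division control protein 11	dR35
DIP2	Q12220	U3 small nucleolar RNA-associated protein 12	mK350
DNF1	P32660	Probable phospholipid-transporting ATPase DNF1	mK541
ECM29	P38737	Proteasome component ECM29	mR542,dR1112
EDE1	P34216	EH domain-containing and endocytosis protein 1	mR252
EMG1	Q06287	Essential for mitotic growth 1	mK147
ERB1	Q04660	Ribosome biogenesis protein ERB1	mK577,mK581
FKS1	P38631	1,3-beta-glucan synthase component FKS1	mR946,dR946,dR952,mR962,dR962,dR1527
GCD10	P41814	tRNA (adenine-N(1)-)-methyltransferase non-catalytic subunit TRM6	mK436,mR447
GCN1	P33892	Translational activator GCN1	dK1446
GCN20	P43535	Protein GCN20	dK656
GUS1	P46655	Glutamyl-tRNA synthetase, cytoplasmic	mR371
HAS1	Q03532	ATP-dependent RNA helicase HAS1	dK444
IMD3	P50095	Probable inosine-5'-monophosphate dehydrogenase IMD3	mR168
ISW1	P38144	ISWI chromatin-remodeling complex ATPase ISW1	mK14
LEA1	Q08963	U2 small nuclear ribonucleoprotein A'	dR141
MPG1	P41940	Mannose-1-phosphate guanyltransferase	dK299
MRPL17	P36528	54S ribosomal protein L17, mitochondrial precursor	mK70
MRPL20	P22354	54S ribosomal protein L20, mitochondrial precursor	mK104
NIP1	P32497	Eukaryotic translation initiation factor 3 subunit C	mK514
NOC2	P39744	Nucleolar complex protein 2	mK384
NOG2	P53742	Nucleolar GTP-binding protein 2	dR336
NOT1	P25655	General negative regulator of transcription subunit 1	mR256
POL12	P38121	DNA polymerase alpha subunit B	mK84
PRP43	P53131	Pre-mRNA-splicing factor ATP-dependent RNA helicase PRP43	dK662
PRT1	P06103	Eukaryotic translation initiation factor 3 subunit B	mR572
PSD2	P53037	Phosphatidylserine decarboxylase proenzyme 2 precursor	mR252
PYK1	P00549	Pyruvate kinase 1	mR216,dR216
RPA2	P22138	DNA-directed RNA polymerase I subunit RPA2	dK513
RPB2	P08518	DNA-directed RNA polymerase II subunit RPB2	mR496
RPL16A	P26784	60S ribosomal protein L16-A	dK148
RPL18A;RPL18B	P07279	60S ribosomal protein L18	mR105
RPL1A;RPL1B	P53030	60S ribosomal protein L1	dK207
RPL20A;RPL20B	P0C2I0	60S ribosomal protein L20	dK47
RPL27A;RPL27B	P0C2H6;P0C2H7	60S ribosomal protein L27	dR15,dK133
RPL2A;RPL2B	P05736	60S ribosomal protein L2	dR21
RPL3	P14126	60S ribosomal protein L3	mR275,dK384
RPL4A	P10664	60S ribosomal protein L4-A	dR84,mK104
RPL7A	P05737	60S ribosomal protein L7-A	mR218
RPL7B	Q12213	60S ribosomal protein L7-B	mR218
RPL8B	P29453	60S ribosomal protein L8-B	mK15,mK43,dK241
RPN2	P32565	26S proteasome regulatory subunit RPN2	mK376
RPS11A;RPS11B	P26781	40S ribosomal protein S11	mR67
RPS13	P05756	40S ribosomal protein S13	mK140
RPS17A	P02407	40S ribosomal protein S17-A	dK59
RRP5	Q05022	rRNA biogenesis protein RRP5	dR215,dK769
RSC1	P53236	Chromatin structure-remodeling complex subunit RSC1	mR454
RSC30	P38781	Chromatin structure-remodeling complex protein RSC30	mR692
RVB2	Q12464	RuvB-like protein 2	mK412
SKI3	P17883	Superkiller protein 3	dK1088
SMB1	P40018	Small nuclear ribonucleoprotein-associated protein B	mK138,mK145
SNF2	P22082	Transcription regulatory protein SNF2	dK1028
SNU114	P36048	114 kDa U5 small nuclear ribonucleoprotein component	dK356,mK935
SSB1	P11484	Heat shock protein SSB1	dR513
SSB2	P40150	Heat shock protein SSB2	dR513
TDH3	P00359	Glyceraldehyde-3-phosphate dehydrogenase 3	dR11
TIF32	P38249	Eukaryotic translation initiation factor 3 subunit A	dK192
TUB2	P02557	Tubulin beta chain	dR318
URA7	P28274	CTP synthase 1	dK28
USO1	P25386	Intracellular protein transport protein USO1	mK119
UTP22	P53254	U3 small nucleolar RNA-associated protein 22	mK1158
VPS52	P39904	Vacuolar protein sorting-associated protein 52	mR224
YKU70	P32807	ATP-dependent DNA helicase II subunit 1	dR549
YPR097W	Q06839	PX domain-containing protein YPR097W	dK249
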