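motif_class	gene	accession	site	provenance	window
MK	GCD10	P41814	mK436	findmod	RGKLHPLMTMKGGGGYLMWCH
MK	PFK2	P16862	mK180	literature	HSYTDLAYRMKTTDTYPSLPK
MK	RPL23A	P04451	dK110	literature	GVIANPKGEMKGSAITGPVGK
MK	RPS17A	P02407	dK59	findmod	KIAGYTTHLMKRIQKGPVRGI
MK	RVB2	Q12464	mK412	findmod	LISVAQQIAMKRKNNTVEVED
MK	URA7	P28274	dK28	findmod	VLASSTGMLMKTLGLKVTSIK
MK	USO1	P25386	mK119	findmod	NGKYPSPLVMKQEKEQVDQFS
RGX_RXG	ECM29	P38737	dR1112	findmod	LAKSSALWSSRKGIAFGLGAI
RGX_RXG	GUS1	P46655	dR371	findmod	IYRCNLTPHHRTGSTWKIYPT
RGX_RXG	RPL27B	P38706	dR15	findmod	LKAGKVAVVVRGRYAGKKVVI
RGX_RXG	RPL4A	P10664	dR84	findmod	IPRVGGGGTGRSGQGAFGNMC
RGX_RXG	RPS11B	P26781	dR67	findmod	KCPFTGLVSIRGKILTGTVVS
RGX_RXG	TDH3	P00359	dR11	findmod	MVRVAINGFGRIGRLVMRIAL
RGX_RXG	TUB2	P02557	dR318	findmod	GRYLTVAAFFRGKVSVKEVED
WXXXR_GXXR	CDC11	P32458	dR35	findmod	VMIVGQSGSGRSTFINTLCGQ
WXXXR_GXXR	ECM29	P38737	mR542	findmod	ARLFNIWGTVRTNRFDIIEES
WXXXR_GXXR	FKS1	P38631	mR946	findmod	TLRTRIWASLRSQTLYRTISG
WXXXR_GXXR	FKS1	P38631	dR946	findmod	TLRTRIWASLRSQTLYRTISG
WXXXR_GXXR	FKS1	P38631	dR1527	findmod	YHRNSWIGYVRMSRARITGFK
WXXXR_GXXR	RPL4A	P10664	dR84	findmod	IPRVGGGGTGRSGQGAFGNMC
WXXXR_GXXR	RPL7A;RPL7B	P05737	mR218	findmod	SNPSGGWGVPRKFKHFIQGGS
WXXXR_GXXR	RSC30	P38781	mR692	findmod	SIKSFSSGNNRFHSNGKEFLF
WXXXR_GXXR	TDH3	P00359	dR11	findmod	MVRVAINGFGRIGRLVMRIAL
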