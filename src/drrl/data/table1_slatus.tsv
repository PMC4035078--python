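name	from	to	strand	class	anticodon	start_codon	stop_codon	intergenic
trnF	1	68	H	tRNA	GAA			0
rrnS	69	1020	H	rRNA				0
trnV	1021	1092	H	tRNA	TAC			0
rrnL	1093	2805	H	rRNA				0
trnL1	2806	2879	H	tRNA	TAA			0
ND1	2880	3854	H	CDS		ATG	TAA	3
trnI	3858	3927	H	tRNA	GAT			-2
trnQ	3926	3997	L	tRNA	TTG			0
CR1	3998	4890	H	CR				1
trnC	4892	4958	L	tRNA	GCA			0
trnY	4959	5026	L	tRNA	GTA			80
trnS1	5107	5177	L	tRNA	TGA			85
trnK	5263	5337	H	tRNA	TTT			43
trnR	5381	5450	H	tRNA	TCG			88
trnS2	5539	5605	H	tRNA	GCT			75
ND5	5681	7519	H	CDS		ATG	TAG	-4
ND6	7516	8037	L	CDS		ATG	TAG	0
trnE	8038	8106	L	tRNA	TTC			4
CYTB	8111	9251	H	CDS		ATG	T	0
trnT	9252	9321	H	tRNA	TGT			86
trnM	9408	9476	H	tRNA	CAT			0
ND2	9477	10521	H	CDS		ATG	T	0
trnW	10522	10591	H	tRNA	TCA			1
trnA	10593	10660	L	tRNA	TGC			1
trnN	10662	10734	L	tRNA	GTT			59
COI	10794	12344	H	CDS			TAA	22
trnD	12367	12434	H	tRNA	GTC			5
COII	12440	13138	H	CDS		ATG	AGA	62
ATP8	13201	13368	H	CDS		ATG	TAA	-10
ATP6	13359	14042	H	CDS		ATG	TAA	-1
COIII	14042	14827	H	CDS		ATG	TAA	-1
trnG	14827	14896	H	tRNA	TCC			0
ND3	14897	15247	H	CDS		ATG	TAA	70
ND4L	15318	15614	H	CDS		ATG	TAA	-7
ND4	15608	16981	H	CDS		ATG	AGA	7
trnH	16989	17057	H	tRNA	GTG			16
trnL2	17074	17147	H	tRNA	TAG			0
CR2	17148	18046	H	CR				0
trnC'	18047	18113	L	tRNA	GCA			0
trnY'	18114	18181	L	tRNA	GTA			78
trnP	18260	18330	L	tRNA	TGG			0
NC	18331	18706	H	NC				0
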