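# Gene table of the Tarsiger indicus mitogenome (GenBank OR459825, 16,723 bp).
# Coordinates are 1-based inclusive; strand + is the heavy strand.
gene	start	end	strand	category	length	start_codon	stop_codon	anticodon
trnF	1	68	+	tRNA	68			gaa
rrnS	69	1050	+	rRNA	982
trnV	1051	1120	+	tRNA	70			uac
rrnL	1121	2719	+	rRNA	1599
trnL2	2720	2794	+	tRNA	75			uaa
ND1	2800	3777	+	PCG	978	ATG	AGA
trnI	3787	3858	+	tRNA	72			gau
trnQ	3866	3936	-	tRNA	71			uug
trnM	3936	4004	+	tRNA	69			cau
ND2	4005	5044	+	PCG	1040	GTG	TA
trnW	5045	5115	+	tRNA	71			uca
trnA	5117	5185	-	tRNA	69			ugc
trnN	5190	5262	-	tRNA	73			guu
trnC	5263	5329	-	tRNA	67			gca
trnY	5329	5399	-	tRNA	71			gua
COX1	5401	6951	+	PCG	1551	GTG	AGG
trnS2	6943	7017	-	tRNA	75			uga
trnD	7021	7089	+	tRNA	69			guc
COX2	7098	7781	+	PCG	684	ATG	TAA
trnK	7783	7850	+	tRNA	68			uuu
ATP8	7852	8019	+	PCG	168	ATG	TAA
ATP6	8010	8693	+	PCG	684	ATG	TAA
COX3	8699	9482	+	PCG	784	ATG	T
trnG	9483	9551	+	tRNA	69			ucc
ND3	9552	9902	+	PCG	351	ATG	TAA
trnR	9904	9973	+	tRNA	70			ucg
ND4L	9975	10271	+	PCG	297	ATG	TAA
ND4	10265	11642	+	PCG	1378	ATG	T
trnH	11643	11713	+	tRNA	71			gug
trnS1	11714	11780	+	tRNA	67			gcu
trnL1	11780	11850	+	tRNA	71			uag
ND5	11851	13668	+	PCG	1818	ATG	AGA
Cytb	13677	14819	+	PCG	1143	ATG	TAA
trnT	14823	14891	+	tRNA	69			ugu
trnP	14899	14968	-	tRNA	70			ugg
ND6	14982	15500	-	PCG	519	ATG	TAG
trnE	15502	15573	-	tRNA	72			uuc
D-loop	15574	16723	+	control-region	1150
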