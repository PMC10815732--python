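# Gene table of the Tarsiger cyanurus mitogenome (GenBank KF997864, 16,803 bp).
# Coordinates are 1-based inclusive; strand + is the heavy strand.
# The printed trnS1 length (65) matches its coordinates here; the published
# comparison table carries a known length-column inconsistency for this gene.
gene	start	end	strand	category	length	start_codon	stop_codon	anticodon
trnF	1	68	+	tRNA	68			gaa
rrnS	69	1051	+	rRNA	983
trnV	1052	1121	+	tRNA	70			uac
rrnL	1122	2723	+	rRNA	1602
trnL2	2724	2798	+	tRNA	75			uaa
ND1	2804	3781	+	PCG	978	ATG	AGA
trnI	3794	3865	+	tRNA	72			gau
trnQ	3873	3943	-	tRNA	71			uug
trnM	3943	4011	+	tRNA	69			cau
ND2	4012	5051	+	PCG	1040	GTG	TA
trnW	5052	5122	+	tRNA	71			uca
trnA	5124	5192	-	tRNA	69			ugc
trnN	5197	5269	-	tRNA	73			guu
trnC	5270	5336	-	tRNA	67			gca
trnY	5336	5406	-	tRNA	71			gua
COX1	5408	6958	+	PCG	1551	GTG	AGG
trnS2	6950	7024	-	tRNA	75			uga
trnD	7028	7096	+	tRNA	69			guc
COX2	7104	7787	+	PCG	684	ATG	TAA
trnK	7789	7856	+	tRNA	68			uuu
ATP8	7858	8025	+	PCG	168	ATG	TAA
ATP6	8016	8699	+	PCG	684	ATG	TAA
COX3	8705	9488	+	PCG	784	ATG	T
trnG	9489	9557	+	tRNA	69			ucc
ND3	9558	9908	+	PCG	351	ATG	TAA
trnR	9910	9979	+	tRNA	70			ucg
ND4L	9981	10277	+	PCG	297	ATG	TAA
ND4	10271	11648	+	PCG	1378	ATG	T
trnH	11649	11719	+	tRNA	71			gug
trnS1	11722	11786	+	tRNA	65			gcu
trnL1	11786	11856	+	tRNA	71			uag
ND5	11857	13674	+	PCG	1818	ATG	AGA
Cytb	13683	14825	+	PCG	1143	ATG	TAA
trnT	14829	14897	+	tRNA	69			ugu
trnP	14904	14973	-	tRNA	70			ugg
ND6	14990	15508	-	PCG	519	ATG	AGG
trnE	15510	15581	-	tRNA	72			uuc
D-loop	15582	16803	+	control-region	1222
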