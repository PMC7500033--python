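name	start	end	category
control_region	16024	576	control_region
7S3	16070	16070	origin
oriL	5780	5780	origin
PH1	561	561	promoter
PL	407	407	promoter
TRNF	577	647	tRNA
RNR1	648	1601	rRNA
TRNV	1602	1670	tRNA
RNR2	1671	3229	rRNA
TRNL1	3230	3304	tRNA
ND1	3307	4262	gene
TRNI	4263	4331	tRNA
TRNQ	4329	4400	tRNA
TRNM	4402	4469	tRNA
ND2	4470	5511	gene
TRNW	5512	5579	tRNA
TRNA	5587	5655	tRNA
TRNN	5657	5729	tRNA
TRNC	5761	5826	tRNA
TRNY	5826	5891	tRNA
CO1	5904	7445	gene
TRNS1	7446	7514	tRNA
TRND	7518	7585	tRNA
CO2	7586	8269	gene
TRNK	8295	8364	tRNA
ATP8	8366	8572	gene
ATP6	8527	9207	gene
CO3	9207	9990	gene
TRNG	9991	10058	tRNA
ND3	10059	10404	gene
TRNR	10405	10469	tRNA
ND4L	10470	10766	gene
ND4	10760	12137	gene
TRNH	12138	12206	tRNA
TRNS2	12207	12265	tRNA
TRNL2	12266	12336	tRNA
ND5	12337	14148	gene
ND6	14149	14673	gene
TRNE	14674	14742	tRNA
CYTB	14747	15887	gene
TRNT	15888	15953	tRNA
TRNP	15956	16023	tRNA
TERM	3229	3256	terminator
major_arc	5781	16069	arc
minor_arc	16071	5779	arc
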