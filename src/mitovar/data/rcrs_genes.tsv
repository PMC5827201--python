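name	start	end	kind	orientation	complex
TRNF	577	647	tRNA	forward	none
RNR1	648	1601	rRNA	forward	none
TRNV	1602	1670	tRNA	forward	none
RNR2	1671	3229	rRNA	forward	none
TRNL1	3230	3304	tRNA	forward	none
ND1	3307	4262	protein	forward	I
TRNI	4263	4331	tRNA	forward	none
TRNQ	4329	4400	tRNA	reverse	none
TRNM	4402	4469	tRNA	forward	none
ND2	4470	5511	protein	forward	I
TRNW	5512	5579	tRNA	forward	none
TRNA	5587	5655	tRNA	reverse	none
TRNN	5657	5729	tRNA	reverse	none
TRNC	5761	5826	tRNA	reverse	none
TRNY	5826	5891	tRNA	reverse	none
COI	5904	7445	protein	forward	IV
TRNS1	7446	7514	tRNA	reverse	none
TRND	7518	7585	tRNA	forward	none
COII	7586	8269	protein	forward	IV
TRNK	8295	8364	tRNA	forward	none
ATP8	8366	8572	protein	forward	V
ATP6	8527	9207	protein	forward	V
COIII	9207	9990	protein	forward	IV
TRNG	9991	10058	tRNA	forward	none
ND3	10059	10404	protein	forward	I
TRNR	10405	10469	tRNA	forward	none
ND4L	10470	10766	protein	forward	I
ND4	10760	12137	protein	forward	I
TRNH	12138	12206	tRNA	forward	none
TRNS2	12207	12265	tRNA	forward	none
TRNL2	12266	12336	tRNA	forward	none
ND5	12337	14148	protein	forward	I
ND6	14149	14673	protein	reverse	I
TRNE	14674	14742	tRNA	reverse	none
CYB	14747	15887	protein	forward	III
TRNT	15888	15953	tRNA	forward	none
TRNP	15956	16023	tRNA	reverse	none
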