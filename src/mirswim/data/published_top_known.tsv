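name	sequence	length	count_HIST	count_NC	family	orthologs
let-7c	TGAGGTAGTAGGTTGTATGGTT	22	2314478	1205674	let-7	hsa odi pma csa cin
miR-9a-5p	TCTTTGGTTATCTAGCTGTATGA	23	1889962	1416714	mir-9	dme
let-7f	TGAGGTAGTAGATTGTATAGTT	22	1754130	1414639	let-7	hsa
miR-378	ACTGGACTTGGAGTCAGAAGGC	22	1544707	1452656	mir-378	hsa ppy cfa
miR-143	TGAGATGAAGCACTGTAGCT	20	1526043	1139450	mir-143	rno mmu xtr pma
miR-182	TTTGGCAATGGTAGAACTCACACCG	25	1638730	326627	mir-182	sko lgi cte mmu eca dre hsa spu
miR-9	TCTTTGGTTATCTAGCTGTATG	22	1103879	751193	mir-9	egr sko bma xtr
let-7	TGAGGTAGTAGGTTGTATAGTT	22	804332	490827	let-7	cel aga sja spu
miR-30a	TGTAAACATCCTCGACTGGAAGC	23	607712	488589	mir-30	hsa dre oan
miR-30d	TGTAAACATCCCCGACTGGAAGC	23	594387	413656	mir-30	hsa pma oan bta
let-7b	TGAGGTAGTAGGTTGTGTGGTT	22	638961	307685	let-7	hsa odi pma xtr cin
miR-127	TCGGATCCGTCTGAGCTTGGC	21	491449	399720	mir-127	mmu oar
miR-183	TATGGCACTGGTAGAATTCACT	22	623293	125748	mir-183	lgi mmu gga sko csa
let-7-5p	TGAGGTAGTAGGTTGTATAGT	21	339133	220610	let-7	tca dme
miR-103a	AGCAGCATTGTACAGGGCTATGA	23	280569	274894	mir-103	hsa pma
miR-24	TGGCTCAGTTCAGCAGGAACAGT	23	308093	212293	mir-24	hsa cfa
miR-26a	TTCAAGTAATCCAGGATAGG	20	285016	218341	mir-26	hsa gga
miR-379	TGGTAGACTATGGAACGTAGG	21	272494	226457	mir-379	hsa
miR-99b	CACCCGTAGAACCGACCTTGC	21	279118	167000	mir-99	mmu
let-7g	TGAGGTAGTAGTTTGTACAGTT	22	227155	185745	let-7	mmu gga xtr dre
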