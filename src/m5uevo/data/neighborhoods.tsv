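anchor	offset	ortholog_family	strand
MCAP_0476	-2	ffh	+
MCAP_0476	-1	ftsY	+
MCAP_0476	1	rpsP	+
MCAP_0476	2	rimM	+
MCAP_0476	3	trmD	+
Mesoplasma_florum_rlmFO	-2	ffh	+
Mesoplasma_florum_rlmFO	-1	ftsY	+
Mesoplasma_florum_rlmFO	1	rpsP	+
Mesoplasma_florum_rlmFO	2	rimM	+
Mesoplasma_florum_rlmFO	3	trmD	+
Mycoplasma_auris_rlmFO	-2	ffh	+
Mycoplasma_auris_rlmFO	-1	ftsY	+
Mycoplasma_auris_rlmFO	1	rpsP	+
Mycoplasma_auris_rlmFO	2	rimM	+
Mycoplasma_auris_rlmFO	3	nusB	+
Mycoplasma_putrefaciens_rlmFO	-2	ffh	+
Mycoplasma_putrefaciens_rlmFO	-1	ftsY	+
Mycoplasma_putrefaciens_rlmFO	1	rpsP	+
Mycoplasma_putrefaciens_rlmFO	2	rimM	+
Mycoplasma_putrefaciens_rlmFO	3	trmD	+
Mycoplasma_yeatsii_rlmFO	-1	ftsY	+
Mycoplasma_yeatsii_rlmFO	1	rpsP	+
Mycoplasma_yeatsii_rlmFO	2	rimM	+
Mycoplasma_yeatsii_rlmFO	3	trmD	+
Mycoplasma_yeatsii_rlmFO	-2	rpsB	+
Mycoplasma_mycoides_subsp_capri_rlmFO	-2	ffh	+
Mycoplasma_mycoides_subsp_capri_rlmFO	-1	ftsY	+
Mycoplasma_mycoides_subsp_capri_rlmFO	1	rpsP	+
Mycoplasma_mycoides_subsp_capri_rlmFO	2	rimM	+
Mycoplasma_mycoides_subsp_capri_rlmFO	3	trmD	+
Mycoplasma_leachii_rlmFO	-2	ffh	+
Mycoplasma_leachii_rlmFO	-1	ftsY	+
Mycoplasma_leachii_rlmFO	1	rpsP	+
Mycoplasma_leachii_rlmFO	2	rimM	+
Mycoplasma_leachii_rlmFO	3	trmD	+
SPICI_rlmFO_ps	-2	ffh	+
SPICI_rlmFO_ps	-1	ftsY	+
SPICI_rlmFO_ps	1	rpsP	+
SPICI_rlmFO_ps	3	trmD	+
SPICI_rlmFO_ps	2	tmk	+
BSU16130	-2	xseA	+
BSU16130	-1	xseB	+
BSU16130	1	dxs	+
BSU16130	2	ispA	+
BSU16130	3	recO	+
ACL_trmFO_1	-2	xseA	+
ACL_trmFO_1	-1	xseB	+
ACL_trmFO_1	1	dxs	+
ACL_trmFO_1	2	ispA	+
ACL_trmFO_1	3	mraZ	+
ACL_trmFO_2	-1	xseB	+
ACL_trmFO_2	1	dxs	+
ACL_trmFO_2	2	ispA	+
ACL_trmFO_2	-2	ktrA	+
ACL_trmFO_2	3	mraZ	+
Mesoplasma_florum_trmFO	-2	xseA	+
Mesoplasma_florum_trmFO	-1	xseB	+
Mesoplasma_florum_trmFO	1	dxs	+
Mesoplasma_florum_trmFO	2	ispA	+
Mesoplasma_florum_trmFO	3	recO	+
Mycoplasma_putrefaciens_trmFO	-2	xseA	+
Mycoplasma_putrefaciens_trmFO	-1	xseB	+
Mycoplasma_putrefaciens_trmFO	2	ispA	+
Mycoplasma_putrefaciens_trmFO	3	recO	+
Mycoplasma_putrefaciens_trmFO	1	gpsA	+
Mycoplasma_yeatsii_trmFO	-2	xseA	+
Mycoplasma_yeatsii_trmFO	-1	xseB	+
Mycoplasma_yeatsii_trmFO	1	dxs	+
Mycoplasma_yeatsii_trmFO	2	ispA	+
Mycoplasma_yeatsii_trmFO	3	recO	+
SPICI_trmFO_ps	-2	xseA	+
SPICI_trmFO_ps	1	dxs	+
SPICI_trmFO_ps	2	ispA	+
SPICI_trmFO_ps	3	recO	+
SPICI_trmFO_ps	-1	soj	+
MCAP_0613	1	folT	+
MCAP_0613	-1	pdhA	+
MCAP_0613	2	glpK	+
MCAP_0613	-2	uvrA	+
MCAP_0613	3	deoC	+
Mycoplasma_putrefaciens_trmFO_like	1	folT	+
Mycoplasma_putrefaciens_trmFO_like	-1	pdhA	+
Mycoplasma_putrefaciens_trmFO_like	-2	uvrA	+
Mycoplasma_putrefaciens_trmFO_like	2	oppF	+
Mycoplasma_putrefaciens_trmFO_like	3	gatA	+
Mycoplasma_yeatsii_trmFO_like	1	folT	+
Mycoplasma_yeatsii_trmFO_like	-1	pdhA	+
Mycoplasma_yeatsii_trmFO_like	2	glpK	+
Mycoplasma_yeatsii_trmFO_like	3	deoC	+
Mycoplasma_yeatsii_trmFO_like	-2	ldh	+
Mycoplasma_auris_trmFO_like	1	folT	+
Mycoplasma_auris_trmFO_like	2	glpK	+
Mycoplasma_auris_trmFO_like	-2	uvrA	+
Mycoplasma_auris_trmFO_like	-1	ackA	+
Mycoplasma_auris_trmFO_like	3	ptsG	+
Mycoplasma_mycoides_subsp_capri_trmFO_like	1	folT	+
Mycoplasma_mycoides_subsp_capri_trmFO_like	-1	pdhA	+
Mycoplasma_mycoides_subsp_capri_trmFO_like	2	glpK	+
Mycoplasma_mycoides_subsp_capri_trmFO_like	-2	uvrA	+
Mycoplasma_mycoides_subsp_capri_trmFO_like	3	deoC	+
Mycoplasma_leachii_trmFO_like	1	folT	+
Mycoplasma_leachii_trmFO_like	-1	pdhA	+
Mycoplasma_leachii_trmFO_like	-2	uvrA	+
Mycoplasma_leachii_trmFO_like	3	deoC	+
Mycoplasma_leachii_trmFO_like	2	oppD	+
Mycoplasma_capricolum_subsp_capripneumoniae_trmFO_like	1	folT	+
Mycoplasma_capricolum_subsp_capripneumoniae_trmFO_like	-1	pdhA	+
Mycoplasma_capricolum_subsp_capripneumoniae_trmFO_like	2	glpK	+
Mycoplasma_capricolum_subsp_capripneumoniae_trmFO_like	-2	uvrA	+
Mycoplasma_capricolum_subsp_capripneumoniae_trmFO_like	3	deoC	+
Mycoplasma_agalactiae_trmFO_like	1	folT	+
Mycoplasma_agalactiae_trmFO_like	2	glpK	+
Mycoplasma_agalactiae_trmFO_like	-1	vpmaX	+
Mycoplasma_agalactiae_trmFO_like	-2	gtsA	+
Mycoplasma_agalactiae_trmFO_like	3	p40	+
Mycoplasma_bovis_trmFO_like	1	folT	+
Mycoplasma_bovis_trmFO_like	2	glpK	+
Mycoplasma_bovis_trmFO_like	-1	vspA	+
Mycoplasma_bovis_trmFO_like	-2	gtsA	+
Mycoplasma_bovis_trmFO_like	3	p40	+
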