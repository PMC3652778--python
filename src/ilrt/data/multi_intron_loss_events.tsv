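gene_id	species	position_nt	loss_type	gene_symbol
ENSMUSG00000048222	mouse	3971	adjacent loss	Mfap1b
ENSMUSG00000048222	mouse	4101	adjacent loss	Mfap1b
ENSMUSG00000072910	mouse	209	adjacent loss	Gm16381
ENSMUSG00000072910	mouse	293	adjacent loss	Gm16381
ENSMUSG00000072910	mouse	331	adjacent loss	Gm16381
ENSRNOG00000002935	rat	134	adjacent loss	Ankrd40
ENSRNOG00000002935	rat	283	adjacent loss	Ankrd40
ENSRNOG00000005260	rat	14955	adjacent loss	Acp1
ENSRNOG00000005260	rat	15061	adjacent loss	Acp1
ENSRNOG00000010458	rat	355	adjacent loss	F1M6Y0_RAT
ENSRNOG00000010458	rat	564	adjacent loss	F1M6Y0_RAT
ENSRNOG00000010458	rat	1116	solitary loss	F1M6Y0_RAT
ENSRNOG00000010989	rat	26396	solitary loss	Ipo5
ENSRNOG00000010989	rat	29302	solitary loss	Ipo5
ENSRNOG00000014048	rat	25880	adjacent loss	CYLD_RAT
ENSRNOG00000014048	rat	26022	adjacent loss	CYLD_RAT
ENSRNOG00000014048	rat	26145	adjacent loss	CYLD_RAT
ENSRNOG00000014048	rat	26237	adjacent loss	CYLD_RAT
ENSRNOG00000014048	rat	26304	adjacent loss	CYLD_RAT
ENSRNOG00000014048	rat	26437	adjacent loss	CYLD_RAT
ENSRNOG00000014048	rat	26546	adjacent loss	CYLD_RAT
ENSRNOG00000020266	rat	2756	solitary loss	Eef2
ENSRNOG00000020266	rat	3814	solitary loss	Eef2
ENSRNOG00000020266	rat	4435	solitary loss	Eef2
ENSRNOG00000025637	rat	444	adjacent loss	LOC317471
ENSRNOG00000025637	rat	647	adjacent loss	LOC317471
ENSRNOG00000026046	rat	3972	adjacent loss	Apex2
ENSRNOG00000026046	rat	4237	adjacent loss	Apex2
ENSRNOG00000026046	rat	4384	adjacent loss	Apex2
ENSRNOG00000026046	rat	4454	adjacent loss	Apex2
ENSRNOG00000034071	rat	190	adjacent loss	Chmp4bl1
ENSRNOG00000034071	rat	368	adjacent loss	Chmp4bl1
ENSRNOG00000034071	rat	483	adjacent loss	Chmp4bl1
ENSRNOG00000034071	rat	610	adjacent loss	Chmp4bl1
ENSRNOG00000043377	rat	7246	adjacent loss	Fdps
ENSRNOG00000043377	rat	7369	adjacent loss	Fdps
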