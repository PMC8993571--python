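rsid	gene	chr	pos	effect_allele	eaf	weight	trait
rs2282679	GC	4	71742666	G	0.32	0.36	25ohd
rs10741657	CYP2R1	11	14893332	G	0.64	0.24	25ohd
rs12785878	DHCR7	11	71456403	G	0.55	0.30	25ohd
rs6013897	CYP24A1	20	54125940	A	0.16	0.29	25ohd
rs9277555	HLA-DPB1	6	33087828	G	0.49	0.10	tpoab
rs11675434	TPO	2	1404043	T	0.31	0.09	tpoab
rs301799	RERE	1	8429242	C	0.17	0.07	tpoab
rs3094228	HCP5	6	31462150	G	0.15	0.08	tpoab
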