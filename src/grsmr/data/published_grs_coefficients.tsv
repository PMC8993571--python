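direction	role	beta	se
25ohd->tpoab	exposure	-0.093	0.009
25ohd->tpoab	outcome	0.067	0.033
tpoab->25ohd	exposure	0.345	0.107
tpoab->25ohd	outcome	-0.030	0.031
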