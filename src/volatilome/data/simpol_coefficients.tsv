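group_kind	b_k
intercept	1.79
carbon	-0.438
aromatic_ring	-0.675
carbon_double_bond	-0.105
hydroxyl	-2.23
aldehyde	-1.35
ketone	-0.935
carboxylic_acid	-3.58
ester	-1.20
ether	-0.718
phenol	-2.14
nitro	-2.15
amine_primary	-1.03
amine_secondary	-0.849
amine_tertiary	-0.608
amide	-4.49
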