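# Built-in miniature fragment set: role <TAB> id <TAB> SMILES
# Attachment points are dummy atoms [*:n]; backbone socket maps:
#   1,2 = acid-substituent sockets on B; 3,4 = base sockets on N; 5-7 = decorations.
acid_substituent	a_me	C[*:1]
acid_substituent	a_ph	[*:1]c1ccccc1
acid_substituent	a_mes	[*:1]c1c(C)cc(C)cc1C
acid_substituent	a_c6f5	[*:1]c1c(F)c(F)c(F)c(F)c1F
acid_substituent	a_cf3	FC(F)(F)[*:1]
acid_substituent	a_cl	Cl[*:1]
base_substituent	b_me	C[*:1]
base_substituent	b_et	CC[*:1]
base_substituent	b_ipr	CC(C)[*:1]
base_substituent	b_ph	[*:1]c1ccccc1
backbone	k_ophen	[*:1]B([*:2])c1cc([*:5])ccc1N([*:3])[*:4]
backbone	k_gem	[*:1]B([*:2])CN([*:3])[*:4]
backbone	k_pyrrole	[*:1]B([*:2])c1cccn1[*:3]
backbone	k_azabor	[*:1]B1CCN([*:3])CC1
backbone	k_naph	[*:1]B([*:2])c1cccc2cccc(N([*:3])[*:4])c12
backbone_substituent	s_me	C[*:1]
backbone_substituent	s_f	F[*:1]
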