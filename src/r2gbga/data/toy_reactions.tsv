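id	name	category	weight	reaction_smarts
amide_coupling	Amide coupling (acid + amine)	coupling	1	[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O):3]>>[C:1](=[O:2])[N:3]
suzuki	Suzuki-Miyaura coupling (boronic acid + aryl halide)	coupling	1	[c:1]B(O)O.[c:2][Br,I]>>[c:1][c:2]
buchwald_hartwig	Buchwald-Hartwig amination (aryl halide + amine)	coupling	1	[c:1][Br,I].[NX3;H2,H1;!$(NC=O):2]>>[c:1][N:2]
n_alkylation	N-alkylation (amine + alkyl halide)	substitution	1	[NX3;H2,H1;!$(NC=O):1].[CX4;!$(C=O):2][Br,I]>>[N:1][C:2]
o_alkylation	O-alkylation of phenol (phenol + alkyl halide)	substitution	1	[c:1][OX2H:2].[CX4:3][Br,I]>>[c:1][O:2][C:3]
reductive_amination	Reductive amination (aldehyde/ketone + amine)	coupling	1	[CX3:1]=[OX1].[NX3;H2,H1;!$(NC=O):2]>>[C:1][N:2]
ester_formation	Fischer esterification (acid + alcohol)	coupling	1	[C:1](=[O:2])[OX2H1].[OX2H:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]
ester_hydrolysis	Ester hydrolysis	fgi	1	[C:1](=[O:2])[OX2:3][CX4:4]>>[C:1](=[O:2])[OX2H1].[OX2H1:3][C:4]
nitro_reduction	Nitro reduction to aniline	fgi	1	[c:1][N+](=[O])[O-]>>[c:1][NH2]
sulfonamide_formation	Sulfonamide formation (sulfonyl chloride + amine)	coupling	1	[S:1](=[O:2])(=[O:3])[Cl].[NX3;H2,H1;!$(NC=O):4]>>[S:1](=[O:2])(=[O:3])[N:4]
aromatic_bromination	Aromatic bromination	substitution	1	[c;H1:1]>>[c:1]Br
williamson_ether	Williamson ether synthesis (alcohol + alkyl halide)	substitution	1	[CX4:1][OX2H:2].[CX4:3][Br,I]>>[C:1][O:2][C:3]
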