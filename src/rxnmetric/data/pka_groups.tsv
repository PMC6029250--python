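name	smarts	pka	kind
carboxylic_acid	[OX2H1;+0][CX3]=[OX1]	4.8	acid
phosphate_hydroxyl	[OX2H1;+0][PX4]=[OX1]	6.5	acid
sulfonic_acid	[OX2H1;+0][SX4](=[OX1])=[OX1]	-1.0	acid
thiol	[SX2H1;+0]	8.3	acid
phenol	[OX2H1;+0][c]	10.0	acid
aliphatic_amine_primary	[NX3;H2;+0;!$(N[a]);!$(N[CX3]=[OX1,SX1,NX2]);!$(N[PX4]);!$(N[SX4])]	10.6	base
aliphatic_amine_secondary	[NX3;H1;+0;!$(N[a]);!$(N[CX3]=[OX1,SX1,NX2]);!$(N=*);!$(N[PX4]);!$(N[SX4])]	10.8	base
aliphatic_amine_tertiary	[NX3;H0;+0;!$(N[a]);!$(N[CX3]=[OX1,SX1,NX2]);!$(N=*);!$(N~[!#6]);!$(N[PX4])]	9.8	base
aniline_amine	[NX3;H2;+0;$(N[a])]	4.6	base
guanidine_imine	[NX2;H0,H1;+0;$(N=C([NX3])[NX3])]	12.5	base
imidazole_basic_n	[nX2;H0;+0;$(n1c[nH]cc1),$(n1cc[nH]c1)]	6.0	base
pyridine_n	[nX2;H0;+0;$(n1ccccc1)]	5.2	base
amidine_imine	[NX2;H0,H1;+0;$(N=C[NX3]);!$(N=C([NX3])[NX3])]	11.0	base
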