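[OX2H]
[OX2H][CX4]
[OX2H][c]
[OX2H][CX3]=[OX1]
C(=O)[OH]
[CX3]=[OX1]
[CX3H1]=[OX1]
[CX3](=[OX1])[CX4]
[CX3](=[OX1])[OX2][CX4]
[CX3](=[OX1])[OX2H0]
[CX3](=[OX1])[NX3]
[OX2]([CX4])[CX4]
[OX2]([c])[CX4]
[OX2]([c])[c]
[OX1-]
[OX2r3]
O=C[OX2]C=O
[CX3](=O)[CX3](=O)
[OX2H][CX4][OX2H]
[OX2H][CX4][NX3]
[NX3;H2]
[NX3;H1]([CX4])[CX4]
[NX3]([CX4])([CX4])[CX4]
[NX3;H2][CX4]
[NX3;H2][c]
[NX3][CX3]=[OX1]
[NX3;H1][CX3]=[OX1]
[NX2]=[CX3]
[NX1]#[CX2]
[NX3][NX3]
[NX2]=[NX2]
[NX3][CX3](=[NX2])[NX3]
[NX3+]
[NX4+]
[NX3](=O)=O
[NX3]([OX1-])=O
[NX2]=[OX1]
[NX3;H1][NX3;H2]
[NX3][OX2H]
[NX2]=[CX3][NX3]
[SX2H]
[SX2]([CX4])[CX4]
[SX2][c]
[SX2][SX2]
[CX3]=[SX1]
[SX4](=[OX1])(=[OX1])
[SX4](=[OX1])(=[OX1])[NX3]
[SX4](=[OX1])(=[OX1])[OX2H]
[SX3]=[OX1]
[SX2][CX3]=[OX1]
[PX4](=[OX1])
[PX4](=[OX1])([OX2H])[OX2H]
[PX4](=[OX1])[OX2][CX4]
[PX4](=[OX1])([OX2])[OX2][PX4]
[PX3]
[CX4][F]
[CX4][Cl]
[CX4][Br]
[CX4][I]
[c][F]
[c][Cl]
[c][Br]
[c][I]
[CX4]([F])[F]
[CX4]([F])([F])[F]
c1ccccc1
c1ccncc1
c1ccoc1
c1ccsc1
c1cc[nH]c1
c1cnc[nH]1
c1ncncn1
n1ccccc1C
c1ccc2ccccc2c1
c1ccc2[nH]ccc2c1
c1ccc2ncccc2c1
o1cccc1C
s1cccc1C
[nX3;H1]
[nX2;H0]
[o]
[s]
[c][OX2H]
[c][NX3;H2]
[c][CX3]=[OX1]
[c][CX3](=[OX1])[OX2H]
[c][NX3][CX3]=[OX1]
[c][CX4]
[c][c]([c])[c]
[CX4H3]
[CX4H2]
[CX4H1]
[CX4H0]
[CX3H2]=[CX3]
[CX3]=[CX3]
[CX2]#[CX2]
[CX3]=[CX3][CX3]=[CX3]
[CX3](=[OX1])[CX3]=[CX3]
[CX4]([CX4])([CX4])([CX4])[CX4]
[CX4]([CX4])([CX4])[CX4]
[NX3;H2][CX4H1][CX3](=[OX1])[OX2H]
[CX3](=[OX1])[CX4][NX3]
[OX2H][CX4H1][CX3](=[OX1])[OX2H]
[CX4][OX2][PX4](=[OX1])([OX2H])[OX2H]
[CX3](=[OX1])[SX2][CX4]
[NX3][CX3](=[OX1])[NX3]
[OX2][CX3](=[OX1])[OX2]
[NX3][CX3](=[OX1])[OX2]
[CX4]([OX2H])([OX2H])
[CX4]1[OX2][CX4]1
[CX4]1[CX4][CX4][CX4][CX4][OX2]1
[CX4]1[CX4][CX4][CX4][OX2]1
[#5]
[#9]
[#14]
[#15]
[#16]
[#17]
[#34]
[#35]
[#53]
[#3]
[#11]
[#12]
[#19]
[#20]
[#26]
[#30]
[r3]
[r4]
[r5]
[r6]
[r7]
[r8]
[r9]
[r10]
[r11]
[r12]
[CX4][CX4]
[CX4][CX4][CX4]
[CX4][CX4][CX4][CX4]
[CX4][CX4][CX4][CX4][CX4]
[CX4][CX4][CX4][CX4][CX4][CX4]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4]
C~N
C~O
C~S
C~P
N~O
N~S
O~P
S~S
N~N
O~O
C=C
C#C
C=N
C#N
C=O
C=S
N=N
N=O
S=O
P=O
[+1]
[-1]
[N+]
[O-]
[S-]
[n+]
[NX3H0]
[NX2H1]
[OX2H0]
[SX2H0]
[CX3H0]
[CX2H0]
[cH0]
[nH0]
[CX4H0]([!#6])
[CX4]([!#6])[!#6]
[CX3](=O)[CX4][CX4]
[CX3](=O)[CX4][OX2]
[CX3](=O)[CX4][NX3]
[OX2][CX4][CX4][OX2]
[NX3][CX4][CX4][NX3]
[NX3][CX4][CX4][OX2]
[OX2][CX4][CX4][NX3]
[SX2][CX4][CX4][NX3]
[c][CX4][NX3]
[c][CX4][OX2]
[c][CX4][CX3]=[OX1]
[c]1[c][c][c][c][c]1[OX2][CX4]
[c][SX2]
[c][PX4]
[c][NX2]=[NX2][c]
[c][CX2]#[NX1]
[CX4]1[CX4][CX4][NX3]1
[CX4]1[CX4][CX4][CX4][NX3]1
[CX4]1[CX4][CX4][CX4][CX4][NX3]1
[CX4]1[CX4][CX4][OX2]1
[CX4]1[CX4][CX4][CX4][CX4][SX2]1
[CX4]1[CX4][CX4][CX4][CX4][CX4]1
[CX4]1[CX4][CX4][CX4][CX4]1
[CX4]1[CX4][CX4][CX4]1
[CX4]1[CX4][CX4]1
[CX4]([CX4])([CX4])[OX2H]
[CX4]([CX4])([CX4])[NX3]
[CX4]([c])([c])
[CX4]([CX3]=[OX1])[CX3]=[OX1]
[CX3](=[CX3])[CX3]=[OX1]
[NX3]([CX3]=[OX1])[CX3]=[OX1]
[F,Cl,Br,I]
[CX4]([Cl])[Cl]
[CX3](=[OX1])[Cl]
[CX3](=[OX1])[F,Cl,Br,I]
[SiX4]
[BX3]
[Se]
[CX4][SeX2]
[te]
[As]
[OX2H][CX4][CX4][CX4][OX2H]
[NX3][CX4][CX3](=[OX1])[NX3]
[CX4][OX2][CX4][OX2][CX4]
[CX3]=[CX3][CX3]=[CX3][CX3]=[CX3]
[CX4][SX2][CX4][CX4]
[CX4][NX3][CX4][NX3]
[PX4](=[OX1])([OX2])([OX2])[OX2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4]
[CX4][SX2][CX4]
[c]1[c][c][c]([OX2H])[c][c]1
[NX3][CX3](=[NX2+0,NX3+1])[NX3]
[CX4][CX4][SX2][CX4]
[nX3;H1]1[cX3][cX3][cX3][cX3]1
[CX4]([CX4H3])[CX4H3]
[CX4][CX4]([CX4H3])[CX4H3]
[OX2H][CX4][CX4H3]
c1ncnc2ncnc12
[nX3;H1][cX3]=[OX1]
O=c1cc[nH]c(=O)n1
c1ncc2nc[nH]c2n1
[OX2][CX4]1[CX4][CX4][CX4][OX2]1
[CX4]1([OX2])[OX2][CX4][CX4][CX4]1
[R2]
[R]!@[R]
[R]@[R]@[R]
[cR2]
[CX4R2]
c1ccc2c(c1)cccc2O
C1CCC2CCCCC2C1
*~*~*~*~*~*~*~*~*~*~*
[!#6;!#1]~[!#6;!#1]
[!#6;!#1]~[!#6;!#1]~[!#6;!#1]
[#6]~[!#6;!#1]~[#6]
[!#6;!#1;R]
[#7,#8,#16;R]
[CX4][CX4][OX2]
[CX4][CX4][CX4][OX2]
[CX4][CX4][CX4][CX4][OX2]
[CX4][CX4][CX4][CX4][CX4][OX2]
[CX4][CX4][CX4][CX4][CX4][CX4][OX2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][OX2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][OX2]
[CX4][CX4][NX3]
[CX4][CX4][CX4][NX3]
[CX4][CX4][CX4][CX4][NX3]
[CX4][CX4][CX4][CX4][CX4][NX3]
[CX4][CX4][CX4][CX4][CX4][CX4][NX3]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][NX3]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][NX3]
[CX4][CX4][SX2]
[CX4][CX4][CX4][SX2]
[CX4][CX4][CX4][CX4][SX2]
[CX4][CX4][CX4][CX4][CX4][SX2]
[CX4][CX4][CX4][CX4][CX4][CX4][SX2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][SX2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][SX2]
[CX4][CX4][F,Cl,Br,I]
[CX4][CX4][CX4][F,Cl,Br,I]
[CX4][CX4][CX4][CX4][F,Cl,Br,I]
[CX4][CX4][CX4][CX4][CX4][F,Cl,Br,I]
[CX4][CX4][CX4][CX4][CX4][CX4][F,Cl,Br,I]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][F,Cl,Br,I]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][F,Cl,Br,I]
[CX4][CX4][OX2H]
[CX4][CX4][CX4][OX2H]
[CX4][CX4][CX4][CX4][OX2H]
[CX4][CX4][CX4][CX4][CX4][OX2H]
[CX4][CX4][CX4][CX4][CX4][CX4][OX2H]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][OX2H]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][OX2H]
[CX4][CX4][NX3;H2]
[CX4][CX4][CX4][NX3;H2]
[CX4][CX4][CX4][CX4][NX3;H2]
[CX4][CX4][CX4][CX4][CX4][NX3;H2]
[CX4][CX4][CX4][CX4][CX4][CX4][NX3;H2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][NX3;H2]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][NX3;H2]
[CX4][CX4][CX3]=[OX1]
[CX4][CX4][CX4][CX3]=[OX1]
[CX4][CX4][CX4][CX4][CX3]=[OX1]
[CX4][CX4][CX4][CX4][CX4][CX3]=[OX1]
[CX4][CX4][CX4][CX4][CX4][CX4][CX3]=[OX1]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX3]=[OX1]
[CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX4][CX3]=[OX1]
[CX4][CX4][SX2H]
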