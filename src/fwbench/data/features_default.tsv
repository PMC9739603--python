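name	smarts	interaction_class
HBD1	[#7!H0,#8!H0]	hydrogen-bond
HBD2	[$([#7;!H0]),$([OX2;!H0])]	hydrogen-bond
HBA	[$([OX2H0]),$([OX1]),$([nX2]),$([NX2H0]),$([NX1])]	hydrogen-bond
HP1	[CX4;!$([CX4]~[!#6;!#1])]	hydrophobic
HP2	[CX3]=[CX3]	hydrophobic
HP3	[CX2]#[CX2]	hydrophobic
PIPI	a1aaaaa1	aromatic
PICat	[$([NX4+]),$([NX3+])]	ionic
SaltBridge	[CX3](=[OX1])[OX1-]	ionic
Hal	[Cl,Br,I]	halogen
F	[F]	halogen
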