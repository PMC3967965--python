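allele	position	reagent	strength
C	1058	Pb	strong
C	1059	Pb	strong
C	1060	Pb	strong
C	1061	Pb	strong
C	1062	Pb	strong
C	1063	Pb	strong
G	1045	Pb	weak
G	1046	Pb	weak
G	1047	Pb	weak
G	1048	Pb	weak
G	1049	Pb	weak
G	1054	T1	strong
G	1058	T1	weak
G	1070	T1	weak
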