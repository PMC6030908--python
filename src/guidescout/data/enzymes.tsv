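# Built-in restriction enzymes for cleavage screening: name <TAB> IUPAC site
EcoRI	GAATTC
BamHI	GGATCC
HindIII	AAGCTT
NotI	GCGGCCGC
XhoI	CTCGAG
XbaI	TCTAGA
PstI	CTGCAG
SalI	GTCGAC
SmaI	CCCGGG
KpnI	GGTACC
SacI	GAGCTC
SphI	GCATGC
NcoI	CCATGG
NdeI	CATATG
BglII	AGATCT
SpeI	ACTAGT
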