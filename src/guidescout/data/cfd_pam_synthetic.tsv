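# Synthetic PAM-class penalties for the CFD score (SpCas9 NGG family).
# Keyed by the two bases following the N of an NGG-type PAM. Constructed
# stand-in table (the published supplement is not redistributed here):
# canonical GG is the only unit entry; NAG and NGA carry the familiar
# intermediate tolerance; everything else is near zero.
pam	penalty
AA	0.000
AC	0.000
AG	0.259
AT	0.000
CA	0.000
CC	0.000
CG	0.107
CT	0.000
GA	0.069
GC	0.022
GG	1.000
GT	0.016
TA	0.000
TC	0.000
TG	0.038
TT	0.000
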