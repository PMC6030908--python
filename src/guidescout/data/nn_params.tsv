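# Unified nearest-neighbor duplex parameters: 5'->3' stack, dH (kcal/mol), dS (cal/mol/K).
# Reverse-complement stacks (TT, TG, AC, AG, TC, CC) resolve to the listed pair.
# initGC / initAT are duplex-initiation terms per terminal G:C / A:T pair.
stack	dH	dS
AA	-7.9	-22.2
AT	-7.2	-20.4
TA	-7.2	-21.3
CA	-8.5	-22.7
GT	-8.4	-22.4
CT	-7.8	-21.0
GA	-8.2	-22.2
CG	-10.6	-27.2
GC	-9.8	-24.4
GG	-8.0	-19.9
initGC	0.1	-2.8
initAT	2.3	4.1
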