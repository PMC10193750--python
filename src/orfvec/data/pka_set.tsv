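# pKa values used for Henderson-Hasselbalch net-charge / isoelectric-point
# calculation.  Source: default ionization constants of the EMBOSS suite
# (Rice P., Longden I., Bleasby A. (2000) "EMBOSS: the European Molecular
# Biology Open Software Suite", Trends in Genetics 16(6):276-277; iep tool).
# version: 1
# sign: +1 groups are positively charged below their pKa, -1 groups
#   negatively charged above it.
group	pka	sign
Nterm	8.6	+1
Cterm	3.6	-1
C	8.5	-1
D	3.9	-1
E	4.1	-1
H	6.5	+1
K	10.8	+1
R	12.5	+1
Y	10.1	-1
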