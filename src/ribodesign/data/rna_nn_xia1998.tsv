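# RNA/RNA nearest-neighbor thermodynamic parameters (Watson-Crick stacks),
# Xia et al. 1998, 1 M NaCl reference.
# stack: 5'->3' dinucleotide of one strand; the antiparallel partner is its
# Watson-Crick complement.  Equivalent stacks (reverse complements) share an
# entry; the loader canonicalizes lookups.
# dH in kcal/mol, dS in cal/(mol*K).
# version: 1
stack	dH	dS
AA	-6.82	-19.0
AU	-9.38	-26.7
UA	-7.69	-20.5
CU	-10.48	-27.1
CA	-10.44	-26.9
GU	-11.40	-29.5
GA	-12.44	-32.5
CG	-10.64	-26.7
GG	-13.39	-32.7
GC	-14.88	-36.9
INIT	3.61	-1.5
TERM_AU	3.72	10.5
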