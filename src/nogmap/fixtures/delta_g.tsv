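# Published standard reaction free energies (kJ/mol) for the NOG network.
# reaction (MoleculeCodes, '+'-separated, '->' between sides)	delta_g_kJ_per_mol
X5P+Pi->G3P+AcP+H2O	-44.376
F6P+Pi->E4P+AcP+H2O	-49.666
S7P+Pi->R5P+AcP+H2O	-53.887
XBP+H2O->X5P+Pi	7.386
SBP+H2O->S7P+Pi	0.576
FBP+H2O->F6P+Pi	-0.0322
Gly2P+F6P->X5P+G3P	4.27
F6P+E4P->G3P+S7P	2.72
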