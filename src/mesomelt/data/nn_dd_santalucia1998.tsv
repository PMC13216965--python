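# provenance: SantaLucia (1998) unified oligonucleotide DNA/DNA NN parameters, 1 M NaCl
# kind: DD
# Step labels use the chemistry-explicit pair-dimer convention: dXdY-dXdY is
# the canonical representative of the dimer under the antiparallel dyad
# symmetry (e.g. the usual AA/TT step is dAdT-dAdT, GT/AC is dAdT-dCdG).
# init:<pair> terms apply once per terminal end of that pair class.
nn_label	dH_kcal_mol	dS_cal_molK
dAdT-dAdT	-7.9	-22.2
dAdT-dCdG	-8.4	-22.4
dAdT-dGdC	-7.8	-21.0
dAdT-dTdA	-7.2	-20.4
dCdG-dAdT	-8.5	-22.7
dCdG-dCdG	-8.0	-19.9
dCdG-dGdC	-10.6	-27.2
dGdC-dAdT	-8.2	-22.2
dGdC-dCdG	-9.8	-24.4
dTdA-dAdT	-7.2	-21.3
init:dAdT	2.3	4.1
init:dCdG	0.1	-2.8
sym	0	-1.4
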