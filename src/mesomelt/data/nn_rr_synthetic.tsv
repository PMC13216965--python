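# provenance: synthetic RNA/RNA NN table (NOT a published parameter set) —
# magnitudes chosen to be realistic for RNA duplexes so pipelines can be
# exercised end to end; supply a published RNA NN table for quantitative work.
# kind: RR
nn_label	dH_kcal_mol	dS_cal_molK
rArU-rArU	-6.8	-19.1
rArU-rCrG	-10.4	-26.8
rArU-rGrC	-11.2	-29.4
rArU-rUrA	-9.4	-26.8
rCrG-rArU	-10.5	-27.1
rCrG-rCrG	-13.3	-32.6
rCrG-rGrC	-10.6	-26.6
rGrC-rArU	-12.4	-32.4
rGrC-rCrG	-14.9	-37.0
rUrA-rArU	-7.7	-20.6
init	3.6	-1.5
init:rArU	3.7	10.5
sym	0	-1.4
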