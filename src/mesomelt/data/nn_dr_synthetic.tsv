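# provenance: synthetic DNA/RNA hybrid NN table (NOT a published parameter
# set) — magnitudes chosen to be realistic for hybrid duplexes so pipelines
# can be exercised end to end; supply a published hybrid NN table for
# quantitative work.  Hybrid steps carry no dyad symmetry: all 16 are listed,
# deoxy strand first.
# kind: DR
nn_label	dH_kcal_mol	dS_cal_molK
dArU-dArU	-7.0	-20.5
dArU-dCrG	-9.0	-23.5
dArU-dGrC	-10.5	-27.5
dArU-dTrA	-7.5	-21.5
dCrG-dArU	-8.5	-22.5
dCrG-dCrG	-10.5	-26.0
dCrG-dGrC	-12.0	-30.5
dCrG-dTrA	-8.0	-22.0
dGrC-dArU	-9.5	-25.0
dGrC-dCrG	-11.5	-28.5
dGrC-dGrC	-13.0	-32.5
dGrC-dTrA	-9.0	-24.0
dTrA-dArU	-6.5	-19.0
dTrA-dCrG	-9.5	-25.5
dTrA-dGrC	-10.0	-26.0
dTrA-dTrA	-7.0	-20.0
init	2.0	-1.0
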