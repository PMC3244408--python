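# RNA/RNA nearest-neighbor propagation parameters (Freier et al. 1986,
# 1 M NaCl).  Stack key is the 5'->3' dinucleotide of one strand paired
# with its Watson-Crick complement; equivalent stacks (e.g. AC and GU)
# carry the same values.
# stack	dH_kcal_per_mol	dS_cal_per_K_mol
AA	-6.6	-18.4
AC	-10.2	-26.2
AG	-7.6	-19.2
AU	-5.7	-15.5
CA	-10.5	-27.8
CC	-12.2	-29.7
CG	-8.0	-19.4
CU	-7.6	-19.2
GA	-13.3	-35.5
GC	-14.2	-34.9
GG	-12.2	-29.7
GU	-10.2	-26.2
UA	-8.1	-22.6
UC	-13.3	-35.5
UG	-10.5	-27.8
UU	-6.6	-18.4
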