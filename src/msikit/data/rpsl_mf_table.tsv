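# Published rpsL reporter-assay mutant-frequency table (x1e-5 scale) for
# small-intestine tissue of Msh2+/+ and Msh2-/- mice, control vs 0.15% KBrO3.
# "NA" marks classes reported as not detected / values not printed.
class	wt_control	wt_kbro3	msh2_control	msh2_kbro3
BS_total	0.37	1.0	4.82	4.22
G:C>A:T	0.30	0.53	2.64	2.39
A:T>G:C	NA	0.18	0.94	1.51
G:C>T:A	0.04	0.29	0.37	0.21
G:C>C:G	NA	NA	0.16	0.11
A:T>T:A	0.03	NA	0.22	NA
A:T>C:G	NA	NA	0.49	NA
Indel_total	2.0	2.32	24.79	54.97
1-indel	0.71	1.38	1.18	0.81
1-indel_(A)n	0.06	0.11	22.82	52.69
2-indel_(A)n	NA	NA	0.21	NA
>2bp_indel	1.23	0.83	0.58	1.47
other	NA	0.07	NA	NA
mean_overall	2.37	NA	28.88	58.26
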