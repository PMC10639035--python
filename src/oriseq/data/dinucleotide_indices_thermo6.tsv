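# Nearest-neighbour DNA duplex thermodynamic parameters per dinucleotide step.
# dH (kcal/mol), dS (cal/mol/K) and dG37 = dH - 310.15*dS/1000 (kcal/mol) from
# Breslauer et al. 1986 (BR86) and the unified SantaLucia 1998 set (SL98),
# as distributed in Biopython Bio.SeqUtils.MeltingTemp (DNA_NN1, DNA_NN3).
# Strand-symmetric: P(XY) == P(revcomp(XY)).
index	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
dH_BR86	-9.1	-6.5	-7.8	-8.6	-5.8	-11	-11.9	-7.8	-5.6	-11.1	-11	-6.5	-6	-5.6	-5.8	-9.1
dS_BR86	-24	-17.3	-20.8	-23.9	-12.9	-26.6	-27.8	-20.8	-13.5	-26.7	-26.6	-17.3	-16.9	-13.5	-12.9	-24
dG37_BR86	-1.6564	-1.1344	-1.3489	-1.1874	-1.7991	-2.75	-3.2778	-1.3489	-1.413	-2.819	-2.75	-1.1344	-0.7585	-1.413	-1.7991	-1.6564
dH_SL98	-7.9	-8.4	-7.8	-7.2	-8.5	-8	-10.6	-7.8	-8.2	-9.8	-8	-8.4	-7.2	-8.2	-8.5	-7.9
dS_SL98	-22.2	-22.4	-21	-20.4	-22.7	-19.9	-27.2	-21	-22.2	-24.4	-19.9	-22.4	-21.3	-22.2	-22.7	-22.2
dG37_SL98	-1.0147	-1.4526	-1.2869	-0.8729	-1.4596	-1.828	-2.1639	-1.2869	-1.3147	-2.2323	-1.828	-1.4526	-0.5938	-1.3147	-1.4596	-1.0147
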