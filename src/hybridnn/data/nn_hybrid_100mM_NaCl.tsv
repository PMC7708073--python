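# Nearest-neighbor parameters for RNA/DNA hybrid duplexes in 100 mM NaCl
# (100 mM NaCl, 10 mM Na2HPO4, 1 mM Na2EDTA, pH 7.0)
# Units: dH kcal/mol, dS cal/(mol K), dG37 kcal/mol.
# Initiation enthalpies are constrained to zero (entropy-controlled initiation).
stack	dH	dS	dG37
rAA/dTT	-7.8	-22.9	-0.7
rAC/dGT	-10.1	-27.3	-1.5
rAG/dCT	-9.4	-26.2	-1.3
rAU/dAT	-5.8	-17.5	-0.4
rCA/dTG	-9.8	-27.4	-1.2
rCC/dGG	-9.5	-24.8	-1.7
rCG/dCG	-9.0	-24.3	-1.4
rCU/dAG	-6.1	-17.9	-0.4
rGA/dTC	-8.6	-22.7	-1.5
rGC/dGC	-10.6	-27.7	-2.0
rGG/dCC	-13.3	-35.7	-2.3
rGU/dAC	-9.3	-25.5	-1.4
rUA/dTA	-6.6	-19.7	-0.5
rUC/dGA	-6.5	-16.3	-1.4
rUG/dCA	-8.9	-23.3	-1.6
rUU/dAA	-7.4	-24.3	0.2
init_GC	0	-4.9	2.0
init_AU	0	-7.0	2.6
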