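# Reference screening cohort: 42 patient sera, variant detection by direct MALDI.
# theoretical_printed is transcribed as published; theoretical_corrected fixes the
# Glu89Gln typographical value (-9.90) to the Gln-Glu residue difference (-0.99).
patient	mutation	detected	theoretical_printed	theoretical_corrected	measured
1	Val30Met	+	+32.06	+32.06	+31.95
2	Val30Met	+	+32.06	+32.06	+31.62
3	Val30Met	+	+32.06	+32.06	+31.58
4	Val30Met	+	+32.06	+32.06	+31.30
5	Val30Met	+	+32.06	+32.06	+32.08
6	Val30Met	+	+32.06	+32.06	+31.21
7	Val30Met	+	+32.06	+32.06	+32.51
8	Val30Met	+	+32.06	+32.06	+31.97
9	Val30Met	+	+32.06	+32.06	+31.20
10	Val30Met	+	+32.06	+32.06	+31.53
11	Val30Met	+	+32.06	+32.06	+33.22
12	Val30Met	+	+32.06	+32.06	+32.07
13	Val30Met	+	+32.06	+32.06	+31.77
14	Val30Met	+	+32.06	+32.06	+32.45
15	Val30Met	+	+32.06	+32.06	+31.33
16	Val30Met	+	+32.06	+32.06	+32.46
17	Val30Met	+	+32.06	+32.06	+30.75
18	Val30Met	+	+32.06	+32.06	+31.29
19	Val30Met	+	+32.06	+32.06	+32.73
20	Val30Met	+	+32.06	+32.06	+32.57
21	Val30Met	+	+32.06	+32.06	+31.22
22	Val30Met	+	+32.06	+32.06	+31.54
23	Val30Met	+	+32.06	+32.06	+31.35
24	Val30Met	+	+32.06	+32.06	+31.82
25	Val30Met	+	+32.06	+32.06	+31.72
26	Val30Met	+	+32.06	+32.06	+31.30
27	Val28Ser	+	-12.06	-12.06	-13.25
28	Val28Met	+	+32.06	+32.06	+32.05
29	Gly47Arg	+	+99.13	+99.13	+98.72
30	Thr49Ser	+	-14.03	-14.03	-13.83
31	Thr49Ile	+	+12.05	+12.05	+8.79
32	Gly53Glu	+	+72.06	+72.06	+71.02
33	Thr60Ala	+	-30.03	-30.03	-29.22
34	Glu61Lys	-	-0.94	-0.94	ND
35	Glu61Lys	-	-0.94	-0.94	ND
36	Glu61Lys	-	-0.94	-0.94	ND
37	Lys80Arg	+	+28.01	+28.01	+27.76
38	Gly83Arg	+	+99.13	+99.13	+98.77
39	Glu89Gln	-	-9.90	-0.99	ND
40	Ala97Gly	+	-14.02	-14.02	-13.55
41	Tyr114Ser	+	-76.10	-76.10	-78.98
42	Tyr114Cys	+	-60.03	-60.03	-59.56
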