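# Raw per-residue physico-chemical property values (one row per standard
# amino acid).  Columns, in the order the PPP encoder emits them per window
# position:
#   parker_hydrophilicity    Parker, Guo & Hodges 1986 HPLC hydrophilicity
#   karplus_schulz_flexibility  Karplus & Schulz 1985 B-factor flexibility
#   grantham_polarity        Grantham 1974 polarity
#   ponnuswamy_polarity      Ponnuswamy, Prabhakaran & Manavalan 1980 series
#                            (average surrounding hydrophobicity tabulation)
#   kolaskar_antigenicity    Kolaskar & Tongaonkar 1990 antigenic propensity
# Values are raw as published; min-max normalization to [0,1] across the 20
# residues is applied at load time.
residue	parker_hydrophilicity	karplus_schulz_flexibility	grantham_polarity	ponnuswamy_polarity	kolaskar_antigenicity
A	2.1	1.041	8.1	12.97	1.064
C	1.4	0.960	5.5	14.63	1.412
D	10.0	1.033	13.0	10.85	0.866
E	7.8	1.094	12.3	11.89	0.851
F	-9.2	0.930	5.2	14.00	1.091
G	5.7	1.142	9.0	12.43	0.874
H	2.1	0.982	10.4	12.16	1.105
I	-8.0	0.892	5.2	15.67	1.152
K	5.7	1.093	11.3	11.36	0.930
L	-9.2	0.967	4.9	14.90	1.250
M	-4.2	0.947	5.7	14.39	0.826
N	7.0	1.117	11.6	11.42	0.776
P	2.1	1.055	8.0	11.37	1.064
Q	6.0	1.165	10.5	11.76	1.015
R	4.2	1.038	10.5	11.72	0.873
S	6.5	1.169	9.2	11.23	1.012
T	5.2	1.073	8.6	11.69	0.909
V	-3.7	0.982	5.9	15.71	1.383
W	-10.0	0.925	5.4	13.93	0.893
Y	-1.9	0.961	6.2	13.42	1.161
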