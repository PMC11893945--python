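# Extended nuclide emission table (convenience set).
# Provenance: compiled by hand in the style of standard decay-data
# compilations (ICRP Publication 107-like mean/line energies and intensities);
# values are approximate working inputs, not paper-printed anchors. Alpha
# entries carry intensity-weighted mean line energies; beta entries carry
# (mean, endpoint) pairs. Same TSV dialect as nuclides_anchored.tsv.
# Cf-252 spontaneous fission (3.09%) omitted; alpha edge carries 1.0.
#
# --- Bi-212 chain ---
Bi-212	3630	A	6.207	-	0.3593
Bi-212	3630	B	0.771	2.252	0.6407
Bi-212	BRANCH	Tl-208	0.3593
Bi-212	BRANCH	Po-212	0.6407
Po-212	3.0e-7	A	8.954	-	1.0
Po-212	BRANCH	Pb-208	1.0
Tl-208	183.2	B	0.557	1.796	1.0
Tl-208	183.2	G	2.614	-	0.9975
Tl-208	BRANCH	Pb-208	1.0
Pb-208	stable	NONE	-	-	-
# --- Th-232 (truncated at Ra-228) ---
Th-232	4.418e17	A	4.081	-	1.0
Th-232	BRANCH	Ra-228	1.0
Ra-228	1.814e8	B	0.0072	0.0128	1.0
Ra-228	BRANCH	Ac-228	1.0
Ac-228	22140	B	0.377	1.158	1.0
Ac-228	BRANCH	Th-228	1.0
# --- Cf-252 (truncated at Cm-248) ---
Cf-252	8.347e7	A	6.219	-	0.9691
Cf-252	BRANCH	Cm-248	1.0
Cm-248	1.098e13	A	5.06	-	1.0
Cm-248	BRANCH	Pu-244	1.0
Pu-244	2.525e15	NONE	-	-	-
# --- Th-227 / Ra-223 chain ---
Th-227	1.6157e6	A	5.9	-	1.0
Th-227	BRANCH	Ra-223	1.0
Ra-223	987552	A	5.667	-	1.0
Ra-223	BRANCH	Rn-219	1.0
Rn-219	3.96	A	6.755	-	1.0
Rn-219	BRANCH	Po-215	1.0
Po-215	0.001781	A	7.386	-	1.0
Po-215	BRANCH	Pb-211	1.0
Pb-211	2166	B	0.447	1.367	1.0
Pb-211	BRANCH	Bi-211	1.0
Bi-211	128.4	A	6.55	-	0.9972
Bi-211	BRANCH	Tl-207	0.9972
Bi-211	BRANCH	Po-211	0.0028
Po-211	0.516	A	7.45	-	1.0
Po-211	BRANCH	Pb-207	1.0
Tl-207	286.2	B	0.493	1.418	1.0
Tl-207	BRANCH	Pb-207	1.0
Pb-207	stable	NONE	-	-	-
# --- Th-228 / Ra-224 chain ---
Th-228	6.033e7	A	5.4	-	1.0
Th-228	BRANCH	Ra-224	1.0
Ra-224	313632	A	5.674	-	1.0
Ra-224	BRANCH	Rn-220	1.0
Rn-220	55.6	A	6.288	-	1.0
Rn-220	BRANCH	Po-216	1.0
Po-216	0.145	A	6.778	-	1.0
Po-216	BRANCH	Pb-212	1.0
Pb-212	38304	B	0.102	0.574	1.0
Pb-212	BRANCH	Bi-212	1.0
# --- beta/gamma emitters ---
Sr-90	9.0856e8	B	0.1958	0.546	1.0
Sr-90	BRANCH	Y-90	1.0
Y-90	230580	B	0.9337	2.280	1.0
Y-90	BRANCH	Zr-90	1.0
Zr-90	stable	NONE	-	-	-
Ni-63	3.189e9	B	0.01712	0.0669	1.0
Ni-63	BRANCH	Cu-63	1.0
Cu-63	stable	NONE	-	-	-
I-125	5.132e6	G	0.0355	-	0.0668
I-125	5.132e6	G	0.0274	-	0.69
I-125	5.132e6	G	0.0274	-	0.69
I-125	5.132e6	CE	0.0226	-	0.80
I-125	5.132e6	CE	0.0305	-	0.11
I-125	BRANCH	Te-125	1.0
Te-125	stable	NONE	-	-	-
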