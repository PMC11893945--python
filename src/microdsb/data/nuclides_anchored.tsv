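# Paper-anchored nuclide emission table.
# Every numeric emission value below (alpha energies, intensities, parent
# half-lives) is exactly the number printed in the source publication's text;
# daughters needed only to close the decay graph are declared with NONE lines.
# Dialect:
#   emission row:    nuclide_id <TAB> half_life_s <TAB> particle{A|B|G|CE} <TAB> energy_MeV <TAB> endpoint_MeV_or_dash <TAB> intensity
#   declaration row: nuclide_id <TAB> half_life_s <TAB> NONE <TAB> - <TAB> - <TAB> -
#   branch row:      nuclide_id <TAB> BRANCH <TAB> daughter_id <TAB> fraction
# half_life_s may be the word "stable" (infinite half-life).
# Cf-252: the 3.09% spontaneous-fission branch is omitted by design (neutrons
# and fission fragments are out of model scope); the alpha-decay edge to
# Cm-248 therefore carries fraction 1.0.
Bi-212	3630	A	6.207	-	0.3593
Bi-212	BRANCH	Tl-208	0.3593
Bi-212	BRANCH	Po-212	0.6407
Po-212	3.0e-7	A	8.954	-	1.0
Po-212	BRANCH	Pb-208	1.0
Tl-208	183.2	NONE	-	-	-
Tl-208	BRANCH	Pb-208	1.0
Pb-208	stable	NONE	-	-	-
Th-232	4.418e17	A	4.081	-	1.0
Th-232	BRANCH	Ra-228	1.0
Ra-228	1.814e8	NONE	-	-	-
Cf-252	8.347e7	A	6.219	-	0.9691
Cf-252	BRANCH	Cm-248	1.0
Cm-248	1.098e13	NONE	-	-	-
Th-227	1.6157e6	A	5.9	-	1.0
Th-227	BRANCH	Ra-223	1.0
Ra-223	987552	NONE	-	-	-
Th-228	6.033e7	A	5.4	-	1.0
Th-228	BRANCH	Ra-224	1.0
Ra-224	313632	NONE	-	-	-
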