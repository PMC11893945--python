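# Alpha-particle total stopping power in liquid water (density 1.0 g/cm3).
# Smooth hand-built tabulation consistent with published range-energy anchors
# for alphas in water (CSDA ranges: ~26 um at 4.081 MeV, ~47 um at 6 MeV,
# ~89 um at 8.954 MeV; Bragg-peak stopping ~250 keV/um near 0.7 MeV).
# This is an input fixture (physics stand-in), not a claim of NIST fidelity.
# Columns: energy_MeV <TAB> stopping_power_MeV_per_um
0.001	0.060
0.005	0.110
0.010	0.140
0.050	0.195
0.100	0.220
0.200	0.240
0.400	0.248
0.700	0.250
1.000	0.235
1.500	0.192
2.000	0.160
2.500	0.140
3.000	0.126
3.500	0.1145
4.000	0.1055
4.500	0.0982
5.000	0.0922
5.500	0.0871
6.000	0.0826
6.500	0.0786
7.000	0.0751
7.500	0.0720
8.000	0.0692
8.500	0.0667
9.000	0.0644
9.500	0.0622
10.000	0.0603
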