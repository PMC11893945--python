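# Electron collision stopping power in liquid water (density 1.0 g/cm3).
# Smooth hand-built tabulation consistent with published collision stopping
# powers and CSDA ranges for electrons in water (e.g. ~2.3 keV/um at 10 keV,
# ~0.185 keV/um at 1 MeV; CSDA range ~3.9 mm at 0.93 MeV, ~1.1 cm at 2.28 MeV).
# This is an input fixture (physics stand-in), not a claim of NIST fidelity.
# Columns: energy_MeV <TAB> stopping_power_MeV_per_um
0.001	0.01260
0.002	0.00980
0.005	0.00600
0.010	0.00226
0.020	0.00132
0.050	0.000668
0.100	0.000412
0.200	0.000285
0.500	0.000203
0.700	0.000192
1.000	0.000185
1.500	0.000182
2.000	0.000183
2.500	0.000185
3.000	0.000187
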