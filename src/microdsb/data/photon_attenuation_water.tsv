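# Photon mass attenuation coefficient in liquid water (density 1.0 g/cm3),
# total with coherent scattering. Smooth hand-built tabulation consistent with
# standard (XCOM-style) values. Input fixture (physics stand-in).
# Columns: energy_MeV <TAB> mu_over_rho_cm2_per_g
0.010	5.330
0.015	1.670
0.020	0.810
0.030	0.376
0.040	0.268
0.050	0.227
0.060	0.206
0.080	0.184
0.100	0.171
0.150	0.151
0.200	0.137
0.300	0.119
0.400	0.106
0.500	0.0969
0.600	0.0896
0.800	0.0786
1.000	0.0707
1.250	0.0632
1.500	0.0575
2.000	0.0494
2.500	0.0443
3.000	0.0397
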