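# Compound library: molecular parameters and candidate product channels per reagent ion.
# Polarizabilities (A^3) and dipole moments (D) are representative literature-style
# values for the study compounds and the aromatic transmission-reference mix.
# Product channel lists are semicolon-separated m/z (Th).
name,formula,molar_mass_da,polarizability_A3,dipole_D,products_hydronium,products_nitrosonium,products_dioxygenyl
butanal,C4H8O,72.06,8.2,2.72,73.06;55.05,71.07;43.05;89.08,72.06;44.05
pentanal,C5H10O,86.07,10.0,2.57,87.08;69.07,85.08;57.07,86.07
hexanal,C6H12O,100.09,11.9,2.66,101.10;83.09,99.08;71.09,100.09
heptanal,C7H14O,114.10,13.7,2.58,115.11;97.10,113.10;85.10,114.10
octanal,C8H16O,128.12,15.5,2.52,129.13;111.12,127.11;99.12,128.12
nonanal,C9H18O,142.14,17.3,2.55,143.14;125.13,141.13;113.13,142.14
decanal,C10H20O,156.15,19.1,2.57,157.16;139.15,155.14;137.13;95.09;81.08;67.05;57.07;43.04;41.03;39.02;173.16;191.16,155.14;156.15
butanoic acid,C4H8O2,88.05,8.6,1.65,89.06;71.05;107.07,118.05,43.04;41.04;71.05
pentanoic acid,C5H10O2,102.07,10.4,1.61,103.08;85.06;121.09,132.07,43.04;41.04;71.05
hexanoic acid,C6H12O2,116.08,12.3,1.13,117.09;99.08;71.09;43.05;41.04;29.02;135.09,146.08,43.04;41.04;71.05
phenol,C6H6O,94.04,11.1,1.22,95.05;113.06,94.04,94.04;95.05
4-methyl-phenol,C7H8O,108.06,13.0,1.35,109.06,108.06,108.06;109.06
4-ethyl-phenol,C8H10O,122.07,14.8,1.60,123.08,122.06;108.06,122.06;107.05;123.08
benzene,C6H6,78.05,10.3,0.00,79.05,,
toluene,C7H8,92.06,12.3,0.36,93.07,,
styrene,C8H8,104.06,15.0,0.13,105.07,,
ethylbenzene,C8H10,106.08,14.2,0.59,107.09,,
chlorobenzene,C6H5Cl,112.01,13.0,1.69,113.02,,
1-2-4-trimethylbenzene,C9H12,120.09,16.1,0.30,121.10,,
1-3-dichlorobenzene,C6H4Cl2,145.97,14.2,1.72,146.98,,
1-2-4-trichlorobenzene,C6H3Cl3,179.93,16.0,1.26,180.94,,
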