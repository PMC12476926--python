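site,name,map,geology,elevation,rainfall_cv,terrain_roughness,n_species_wood_density,n_species_lma
CAM,Cambalache,2351.10,V,82.00,28.31,5.40,12,10
CAR,Carite,1545.40,L,577.90,38.25,2.85,15,15
GUA,Guajataca,2068.90,L,221.50,41.71,6.24,14,12
GUN,Guanica,2139.80,V,878.30,54.12,5.61,20,19
GUI,Guilarte,1861.90,V,186.00,59.41,3.13,5,3
LUQ,Luquillo,1728.50,L,1090.80,26.85,3.59,28,27
RIO,Rio Abajo,2220.10,V,317.00,41.61,7.12,15,15
TOR,Toro Negro,1039.30,L,887.30,44.07,3.62,19,19
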