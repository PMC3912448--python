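name,gi_pct,se_gi_pct,ligcell_pct,se_ligcell_pct,rain,se_rain,fires_2000_2008,soil_n_pct,soil_c_pct,soil_p_permil,sand_pct,silt_pct,clay_pct,bulk_density
Balanites,32,14,34.1,2.3,721,86,4,0.19,1.84,32.5,51.0,38.3,10.7,1.31
Barafu,65,4,34.5,1.9,472,31,2,0.26,3.14,1132,27.6,60.6,11.7,0.85
Klein's Camp West,56,9,36.3,2.4,771,61,5,0.22,1.77,5.9,40.6,35.5,23.9,1.07
Kemarische Hills,66,3,31.6,3.1,832,87,4,0.25,2.67,50.0,35.5,52.0,12.5,0.96
Kuka Hills,49,4,37.7,2.4,784,41,5,0.13,2.13,7.5,45.4,46.2,8.40,1.15
Musabi Plains,28,13,37.6,1.9,885,63,7,0.14,2.20,69.2,32.9,31.2,35.9,0.90
Soit Olowotonyi,54,13,35.6,2.1,499,39,4,0.11,1.91,1240,32.1,55.4,12.5,0.84
Tagora Plains,69,12,31.8,2.8,654,87,5,0.15,1.85,61.2,65.8,28.0,6.21,1.22
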