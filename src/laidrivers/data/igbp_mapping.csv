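igbp_code,igbp_name,group
1,evergreen_needleleaf_forest,non_study
2,evergreen_broadleaf_forest,non_study
3,deciduous_needleleaf_forest,non_study
4,deciduous_broadleaf_forest,forest
5,mixed_forest,forest
6,closed_shrubland,non_study
7,open_shrubland,non_study
8,woody_savanna,grassland
9,savanna,grassland
10,grassland,grassland
11,permanent_wetland,non_study
12,cropland,farmland
13,urban_and_built_up,non_study
14,cropland_natural_vegetation_mosaic,farmland
15,snow_and_ice,non_study
16,barren,non_study
17,water,non_study
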