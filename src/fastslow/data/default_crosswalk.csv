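code,class,fraction
10,cropland,1.0
11,cropland,1.0
12,cropland,1.0
20,cropland,1.0
30,cropland,0.7
30,natural_grass,0.3
40,cropland,0.3
40,natural_grass,0.7
50,broadleaf_evergreen_trees,1.0
60,broadleaf_deciduous_trees,1.0
61,broadleaf_deciduous_trees,1.0
62,broadleaf_deciduous_trees,1.0
70,needleleaf_evergreen_trees,1.0
71,needleleaf_evergreen_trees,1.0
72,needleleaf_evergreen_trees,1.0
80,needleleaf_deciduous_trees,1.0
81,needleleaf_deciduous_trees,1.0
82,needleleaf_deciduous_trees,1.0
90,broadleaf_evergreen_trees,0.25
90,broadleaf_deciduous_trees,0.25
90,needleleaf_evergreen_trees,0.25
90,needleleaf_deciduous_trees,0.25
100,broadleaf_deciduous_trees,0.5
100,natural_grass,0.5
110,broadleaf_deciduous_trees,0.3
110,natural_grass,0.7
120,broadleaf_deciduous_shrubs,1.0
121,broadleaf_evergreen_shrubs,1.0
122,broadleaf_deciduous_shrubs,1.0
130,natural_grass,1.0
140,natural_grass,1.0
150,bare_soil,0.85
150,natural_grass,0.15
151,bare_soil,0.85
151,broadleaf_deciduous_trees,0.15
152,bare_soil,0.85
152,broadleaf_deciduous_shrubs,0.15
153,bare_soil,0.85
153,natural_grass,0.15
160,broadleaf_evergreen_trees,0.6
160,water,0.4
170,broadleaf_evergreen_trees,0.6
170,water,0.4
180,natural_grass,0.6
180,water,0.4
190,urban,1.0
200,bare_soil,1.0
201,bare_soil,1.0
202,bare_soil,1.0
210,water,1.0
220,snow_ice,1.0
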