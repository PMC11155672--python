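chemical,group,n_active,n_total,reported_ratio
2-phenylphenol,high,80,976,0.082
benzyldimethyldodecylammonium chloride,high,170,364,0.467
bisphenol A,high,304,1447,0.210
diazinon,high,124,1089,0.114
dimethyl-1-2-dibromo-2-2-dichlorethyl phosphate,high,276,1030,0.268
dicofol,high,306,951,0.322
methylbenzethonium chloride,high,218,446,0.489
didecyldimethylammonium chloride,high,470,973,0.483
norflurazon,high,103,941,0.109
perfluoro nonanoic acid,high,279,1134,0.246
thiabendazole,high,82,956,0.086
triflumizole,high,448,1168,0.384
ethylene glycol butyl ether (EGBE),low,7,817,0.009
hexabromocyclodecane (HBCD),low,197,621,0.317
malathion,low,193,1144,0.169
methylene chloride,low,1,220,0.005
monobenzyl phthalate,low,22,858,0.026
perfluorodecanoic acid,low,320,1077,0.297
permethrin,low,176,1210,0.145
pyraclostrobin,low,388,1198,0.324
retinoic acid (RA),low,305,1054,0.289
tris(1-3-dichloro-2-propyl) phosphate (TDCIPP),low,322,1208,0.267
tetraconazole,low,342,1028,0.333
tetradonium bromide,low,310,616,0.503
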