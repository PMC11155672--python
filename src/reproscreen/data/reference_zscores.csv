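chemical,cas,z_10uM,z_30uM,z_50uM,z_100uM
2-phenylphenol,90-43-7,-0.17755904,-0.835403038,0.527326135,1.050863864
benzyldimethyldodecylammonium chloride,139-07-1,2.78478466,7.52545311,0.830889353,2.25191063
bisphenol A,80-05-7,-0.258125177,-0.346607755,0.127835223,1.002009593
diazinon,332-41-5,NT,0.857304437,NT,1.416176111
dimethyl-1-2-dibromo-2-2-dichlorethyl phosphate,300-76-5,0.532899005,-0.484680664,-0.018537122,1.829875555
dicofol,115-32-2,NT,1.030403236,NT,0.316375902
methylbenzethonium chloride,25115-18-4,6.65914045,6.7145512,7.72694365,5.4143412
didecyldimethylammonium chloride,7173-51-5,1.59554513,1.396318643,0.731390858,0.94670189
norflurazon,375-95-1,NT,0.274425578,NT,6.347934415
perfluoro nonanoic acid,148-98-8,-0.294215382,0.126864892,-0.0514802,1.668737891
thiabendazole,68694-11-1,0.30853793,2.290591694,-0.112301184,3.548542028
tri-p-tert-butylphenyl phosphate,78-33-1,NT,1.137348756,NT,-0.523046153
triflumizole,68694-11-1,1.524173433,0.959842876,0.312115328,1.19880601
ethylene glycol butyl ether (EGBE),111-76-2,-0.493188189,-0.760018538,-0.428279589,-0.786605971
hexabromocyclodecane (HBCD),3194-55-6,-0.532066923,-0.637397676,-0.262285387,-0.635415477
malathion,121-75-5,-0.57865188,-0.633130582,-0.195971923,-0.080772843
methylene chloride,75-09-2,-0.760359221,-0.205061778,-0.145673888,-0.320872732
monobenzyl phthalate,2528-16-7,-0.384659645,-0.081544854,-0.425217575,-0.614814203
perfluorodecanoic acid,335-76-2,-0.760359221,-0.402192131,NDA,-1.219646999
permethrin,52645-53-1,-0.55800923,-0.735099931,-0.198504842,-0.561941711
pyraclostrobin,175013-18-0,-0.436371926,-0.067060827,-0.242144092,-0.523376499
retinoic acid (RA),302-79-4,-0.654868704,-0.096655283,-0.429698571,-0.586138019
tris(1-3-dichloro-2-propyl) phosphate (TDCIPP),13674-87-8,-0.56212385,-0.236069063,-0.422525695,-0.350506139
tetraconazole,112281-77-3,-0.369829188,-0.574755817,-0.344775632,-1.124919234
tetradonium bromide,1119-97-7,-0.760359221,-0.166809423,-0.486457849,-0.864417879
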