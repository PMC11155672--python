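family,count_bottom,count_top,reported_fisher_p,reported_fdr_p
Steroid hormone,11,37,0.000431,0.018115
Cell cycle,480,626,0.007459,0.156631
Gpcr,63,102,0.011238,0.157328
Kinase,16,34,0.019903,0.186766
Deiodinase,11,26,0.022234,0.186766
Apoptosis,1,6,0.081175,0.568227
Dehalogenase,3,9,0.10123,0.607382
Cardiomyocyte function,1,5,0.135322,0.710441
Mitochondria,10,16,0.236846,0.945855
Esterase,10,16,0.236846,0.945855
Hydrolase,2,5,0.270689,0.945855
Neuroactivity,35,45,0.293081,0.945855
Transporter,67,81,0.329758,0.945855
Oxidoreductase,20,26,0.349409,0.945855
growth factor receptor,5,8,0.357916,0.945855
Cytokine receptor,10,14,0.360326,0.945855
Cyp,174,198,0.420697,0.979568
Nuclear receptor,402,447,0.492056,0.979568
Protease inhibitor,9,11,0.503453,0.979568
Ligase,4,5,0.562571,0.979568
Filaments,5,6,0.568756,0.979568
Mutagenicity response,8,9,0.584528,0.979568
DNA binding,233,249,0.663085,0.979568
Misc protein,5,5,0.683913,0.979568
Oxidase,5,5,0.683913,0.979568
Transcription factor,3,3,0.70272,0.979568
Transferase,32,31,0.743804,0.979568
Ion channel,13,12,0.74387,0.979568
Growth factor,33,32,0.744556,0.979568
Catalase,5,4,0.793523,0.979568
Lyase,16,14,0.795718,0.979568
MicroRNA,4,3,0.813002,0.979568
Apolipoprotein,4,3,0.813002,0.979568
Metabolite,21,18,0.830782,0.979568
Phosphatase,17,14,0.841617,0.979568
Cell morphology,33,28,0.877353,0.979568
Cytokine,210,207,0.88397,0.979568
Membrane protein,5,3,0.886276,0.979568
Protease,65,57,0.913858,0.984155
Cell adhesion molecules,105,89,0.971261,1
Malformation,74,28,1,1
Neurodevelopment,226,125,1,1
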