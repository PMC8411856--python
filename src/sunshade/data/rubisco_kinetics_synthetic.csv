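species,pathway,kcat25,kc21_25,sco25,ha_kcat,ha_kc21,ha_sco
Triticum aestivum,C3,3.1,600,2750,58000,66000,22000
Hordeum vulgare,C3,3.6,640,2780,56000,64000,21000
Avena sativa,C3,3.0,590,2730,57500,65500,22500
Oryza sativa,C3,2.9,610,2700,59000,67000,23000
Beta vulgaris,C3,2.7,570,2720,60000,68000,24000
Solanum lycopersicum,C3,2.8,560,2760,61000,69000,23500
Ipomoea batatas,C3,3.0,600,2740,58500,66500,22800
Cucurbita maxima,C3,2.9,580,2710,59500,67500,23200
Lactuca sativa,C3,2.8,575,2700,60500,68500,24500
Spinacia oleracea,C3,3.3,620,2790,55000,63000,20500
Panicum bisulcatum,C3,3.4,630,2850,54000,62000,19500
Nicotiana tabacum,C3,2.6,550,2690,62000,70000,25000
Glycine max,C3,2.7,565,2705,61500,69500,24800
Helianthus annuus,C3,3.2,615,2745,57000,65000,22200
Phaseolus vulgaris,C3,2.8,585,2715,60200,68200,24200
Gossypium hirsutum,C3,2.9,595,2725,59800,67800,23800
Zea mays,C4,4.4,1300,2250,52000,60000,18000
Urochloa panicoides,C4,6.8,1500,2400,48000,57000,16000
Megathyrsus maximus,C4,6.5,1480,2380,48500,57500,16200
Panicum deustum,C4,6.2,1450,2370,49000,58000,16500
Panicum coloratum,C4,4.0,1200,2450,53000,61000,18500
Panicum virgatum,C4,4.8,1350,2300,51000,59500,17500
Saccharum officinarum,C4,5.2,1400,2280,50500,59000,17200
Setaria viridis,C4,5.9,1430,2360,49500,58500,16800
Cenchrus ciliaris,C4,5.7,1420,2350,49800,58800,17000
Sorghum bicolor,C4,4.6,1320,2260,51500,59800,17800
Panicum milioides,C3C4_intermediate,3.8,900,2550,53500,61500,19000
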