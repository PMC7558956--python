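drug,species,state,ara,dose_mg,d50_um,pred_fa_A,pred_fa_B,pred_fa_C,pred_aucr,fa_fdst_pct,gastric_limiting,observed_fa,observed_aucr,pair_id
acalabrutinib,human,fasted,0,100,98,0.54,1.00,0.94,,88,DRL,,,acala-h-fasted-100
acalabrutinib,human,fasted,1,100,98,0.54,0.57,0.56,0.60,6,SL,,0.56,acala-h-fasted-100
albendazole,human,fasted,0,350,3.4,0.10,0.14,0.14,,32,SL,0.11,,
albendazole,human,fasted,0,400,3.4,0.09,0.13,0.13,,30,SL,0.06,,
albendazole,human,fed,0,400,3.4,0.18,0.19,0.19,,8,SL,0.29,,
albendazole,human,fasted,0,700,3.4,0.08,0.10,0.10,,23,SL,0.06,,
albendazole,human,fasted,0,800,3.4,0.07,0.09,0.09,,22,SL,0.10,,
albendazole,human,fasted,0,1400,3.4,0.05,0.07,0.07,,17,SL,0.04,,albend-h-fasted-1400
albendazole,human,fasted,1,1400,3.4,0.05,0.05,0.05,0.83,0,SL,0.03,0.72,albend-h-fasted-1400
albendazole,human,fasted,0,2100,3.4,0.04,0.05,0.05,,15,SL,0.03,,
aprepitant,human,fasted,0,40,0.12,1.00,1.00,1.00,,28,SL,0.90,,
aprepitant,human,fasted,0,100,5.0,0.23,0.36,0.35,,38,SL,0.22,,
aprepitant,human,fasted,0,125,0.12,1.00,1.00,1.00,,11,SL,0.79,,
aprepitant,human,fasted,0,250,0.12,0.96,0.97,0.97,,6,SL,0.86,,
aprepitant,human,fasted,0,375,0.12,0.94,0.95,0.95,,4,SL,0.67,,
aprepitant,human,fasted,0,500,0.12,0.92,0.92,0.92,,3,SL,0.83,,
aprepitant,human,fed,0,125,0.12,1.00,1.00,1.00,,5,SL,1.00,,
aprepitant,dog,fasted,0,20,0.12,0.94,0.98,0.98,,24,SL,1.00,,
aprepitant,dog,fed,0,20,0.12,1.00,1.00,1.00,,61,DRL,1.00,,
aprepitant,dog,fasted,0,20,0.48,0.54,0.72,0.72,,33,SL,0.43,,
aprepitant,dog,fasted,0,20,1.9,0.24,0.46,0.46,,52,SL,0.31,,
aprepitant,dog,fasted,0,20,2.0,0.23,0.45,0.45,,53,SL,0.33,,
aprepitant,dog,fasted,0,20,5.0,0.14,0.37,0.37,,63,SL,0.28,,
aprepitant,dog,fasted,0,20,5.5,0.14,0.36,0.36,,64,SL,0.24,,
aprepitant,dog,fed,0,20,5.5,0.64,0.95,0.94,,64,DRL,0.77,,
aprepitant,dog,fasted,0,20,25,0.08,0.28,0.28,,74,SL,0.18,,
bms,human,fasted,0,150,3.0,0.80,1.00,1.00,,82,DRL,,,bms-h-fasted-150
bms,human,fasted,1,150,3.0,0.80,0.82,0.81,0.81,1,SL,,0.43,bms-h-fasted-150
bms,dog,fasted,0,150,40,0.08,1.00,0.70,,91,DRL,,,bms-d-fasted-150
bms,dog,fasted,1,150,40,0.08,0.09,0.08,0.12,5,SL,,0.03,bms-d-fasted-150
cinnarizine,human,fasted,0,25,25,0.25,0.99,0.96,,98,DRL,0.59,,cinna-h-fasted-25-25
cinnarizine,human,fasted,1,25,25,0.25,0.27,0.26,0.27,1,SL,0.16,0.27,cinna-h-fasted-25-25
cinnarizine,human,fasted,0,25,60,0.08,0.99,0.93,,99,DRL,0.55,,cinna-h-fasted-25-60
cinnarizine,human,fasted,1,25,60,0.08,0.09,0.08,0.09,2,SL,0.08,0.14,cinna-h-fasted-25-60
cinnarizine,human,fasted,0,50,25,0.18,0.99,0.93,,96,DRL,0.81,,
cinnarizine,human,fed,0,50,25,0.38,1.00,0.92,,83,DRL,1.00,,
cinnarizine,human,fasted,0,50,60,0.07,0.98,0.89,,99,DRL,0.55,,
cinnarizine,human,fed,0,50,60,0.19,0.98,0.82,,92,DRL,0.95,,
cinnarizine,dog,fasted,0,25,25,0.05,0.96,0.87,,97,DRL,0.54,,cinna-d-fasted-25-25
cinnarizine,dog,fasted,1,25,25,0.05,0.06,0.05,0.06,2,SL,0.03,0.05,cinna-d-fasted-25-25
danixirin,human,fed,0,50,2.0,0.40,0.91,0.85,,70,DRL,0.35,,
danixirin,human,fasted,0,100,1.8,0.23,0.90,0.83,,80,DRL,0.71,,danix-h-fasted-100
danixirin,human,fasted,1,100,1.8,0.23,0.24,0.24,0.29,2,SL,0.30,0.43,danix-h-fasted-100
danixirin,human,fed,0,100,1.8,0.28,0.75,0.66,,65,SL,0.61,,
dasatinib,human,fasted,0,50,27,0.38,1.00,0.97,,94,DRL,0.85,,
dasatinib,human,fasted,0,70,27,0.32,1.00,0.96,,92,DRL,0.98,,
dasatinib,human,fasted,0,100,27,0.26,0.99,0.93,,91,DRL,0.90,,dasat-h-fasted-100
dasatinib,human,fasted,1,100,27,0.26,0.27,0.26,0.28,1,SL,0.48,0.54,dasat-h-fasted-100
dipyridamole,human,fasted,0,50,75,0.14,0.88,0.82,,95,DRL,0.50,,dipyr-h-fasted-50
dipyridamole,human,fasted,1,50,75,0.14,0.15,0.15,0.18,5,DRL,0.31,0.63,dipyr-h-fasted-50
dipyridamole,dog,fasted,0,50,75,0.04,0.78,0.68,,96,DRL,,,dipyr-d-fasted-50
dipyridamole,dog,fasted,1,50,75,0.04,0.05,0.05,0.07,9,SL,,0.11,dipyr-d-fasted-50
enoxacin,human,fasted,0,400,25,0.59,0.98,0.89,,57,DRL,1.00,,enoxa-h-fasted-400
enoxacin,human,fed,0,400,25,0.81,1.00,0.99,,36,SL,1.00,,
enoxacin,human,fasted,1,400,25,0.59,0.70,0.64,0.64,11,SL,0.67,0.67,enoxa-h-fasted-400
etoricoxib,human,fasted,0,120,40,1.00,1.00,1.00,,78,DRL,1.00,,etori-h-fasted-120
etoricoxib,human,fasted,1,120,40,1.00,1.00,1.00,1.00,13,SL,1.00,1.0,etori-h-fasted-120
gefitinib,human,fasted,0,50,30,0.49,0.99,0.96,,94,DRL,0.74,,
gefitinib,human,fasted,0,100,30,0.38,0.99,0.94,,89,DRL,0.69,,
gefitinib,human,fasted,0,250,30,0.23,0.99,0.81,,83,DRL,0.78,,gefit-h-fasted-250
gefitinib,human,fasted,1,250,30,0.23,0.24,0.23,0.29,0,SL,0.41,0.53,gefit-h-fasted-250
gefitinib,human,fed,0,250,30,1.00,1.00,1.00,,46,SL,0.80,,
gefitinib,human,fasted,0,500,30,0.15,0.98,0.64,,81,DRL,0.80,,
ibrutinib,human,fasted,0,560,10,0.10,0.13,0.13,,21,SL,0.21,,ibrut-h-fasted-560
ibrutinib,human,fasted,1,560,10,0.10,0.10,0.10,0.80,0,SL,0.18,0.87,ibrut-h-fasted-560
ibrutinib,human,fed,0,560,10,0.39,0.40,0.40,,3,SL,0.30,,
ketoconazole,human,fasted,0,200,25,0.26,1.00,0.90,,84,DRL,0.72,,ketoc-h-fasted-200
ketoconazole,human,fasted,1,200,25,0.26,0.27,0.26,0.29,2,SL,0.06,0.09,ketoc-h-fasted-200
ketoconazole,human,fed,0,200,25,0.59,1.00,0.92,,61,DRL,0.56,,
ketoconazole,human,fasted,0,400,25,0.17,1.00,0.75,,83,DRL,0.92,,
ketoconazole,human,fed,0,400,25,0.42,1.00,0.74,,53,SL,1.00,,
ketoconazole,human,fasted,0,800,25,0.14,0.99,0.57,,79,SL,0.86,,
ketoconazole,human,fed,0,800,25,0.32,1.00,0.54,,45,SL,0.87,,
ketoconazole,dog,fasted,0,200,25,0.06,0.99,0.62,,91,DRL,,,ketoc-d-fasted-200
ketoconazole,dog,fasted,1,200,25,0.06,0.07,0.06,0.10,3,SL,,0.03,ketoc-d-fasted-200
palbociclib,human,fasted,0,125,16,0.46,1.00,1.00,,82,DRL,0.90,,palbo-h-fasted-125
palbociclib,human,fasted,1,125,16,0.46,0.58,0.47,0.47,2,SL,0.47,0.52,palbo-h-fasted-125
palbociclib,human,fed,0,125,16,0.81,1.00,1.00,,64,DRL,0.95,,palbo-h-fed-125
palbociclib,human,fed,1,125,16,0.81,0.91,0.82,0.82,2,SL,0.86,0.91,palbo-h-fed-125
posaconazole,human,fed,0,50,1.7,0.63,0.66,0.66,,6,SL,0.57,,
posaconazole,human,fed,0,100,1.7,0.57,0.59,0.59,,3,SL,0.75,,
posaconazole,human,fasted,0,200,1.7,0.08,0.11,0.11,,23,SL,0.19,,posac-h-fasted-200
posaconazole,human,fasted,1,200,1.7,0.08,0.08,0.08,0.78,0,SL,0.18,0.93,posac-h-fasted-200
posaconazole,human,fed,0,200,1.7,0.52,0.53,0.53,,2,SL,0.58,,posac-h-fed-200
posaconazole,human,fed,1,200,1.7,0.52,0.52,0.52,0.99,0,SL,0.49,0.85,posac-h-fed-200
posaconazole,human,fasted,0,400,1.7,0.06,0.07,0.07,,17,SL,0.14,,posac-h-fasted-400
posaconazole,human,fasted,1,400,1.7,0.06,0.06,0.06,0.84,0,SL,0.09,0.66,posac-h-fasted-400
posaconazole,human,fed,0,400,1.7,0.46,0.46,0.46,,1,SL,0.52,,
posaconazole,human,fed,0,800,1.7,0.37,0.37,0.37,,1,SL,0.42,,
posaconazole,human,fed,0,1200,1.7,0.31,0.32,0.32,,1,SL,0.23,,
posaconazole,dog,fasted,0,100,1.7,0.05,0.07,0.07,,26,SL,0.11,,
posaconazole,dog,fed,0,100,1.7,0.29,0.37,0.37,,24,SL,0.40,,
posaconazole,dog,fed,0,400,1.7,0.14,0.16,0.16,,15,SL,0.40,,
posaconazole,dog,fed,0,800,1.7,0.08,0.10,0.10,,13,SL,0.32,,
posaconazole,dog,fed,0,1200,1.7,0.06,0.07,0.07,,12,SL,0.24,,
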