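name,MW,pKa,logPoct,S_buffer,pH_buffer,S_fassif,pH_fassif,Cbm_fassif,S_fassif_dog,pH_fassif_dog,Cbm_fassif_dog,S_fessif,pH_fessif,Cbm_fessif,Papp,Papp_pH
acalabrutinib,466,5.8,2.0,0.048,8.0,0.12,6.5,3.0,,,,,,,,
albendazole,265,4.2,3.1,0.0009,6.5,0.0021,6.5,3.0,,,,,,,,
aprepitant,534,4.2,4.8,0.0008,6.5,0.019,6.5,3.0,0.021,6.5,5.0,0.119,5.0,15.0,,
bms,550,6.3,2.3,0.019,6.6,0.043,6.5,3.0,,,,,,,,
cinnarizine,369,7.5,5.7,0.0014,6.5,0.013,6.5,3.0,,,,0.112,5.0,15.0,,
danixirin,442,4.8,1.2,0.004,6.0,0.009,6.5,3.0,,,,,,,,
dasatinib,488,6.8,3.2,0.01,6.0,0.032,6.5,3.0,,,,,,,,
dipyridamole,505,4.9,3.9,0.006,6.5,0.017,6.5,3.0,,,,,,,,
enoxacin,320,6.2,-0.2,0.38,6.5,0.54,6.5,3.0,,,,0.83,5.8,10.0,6.4e-6,6.5
etoricoxib,359,4.6,3.1,0.16,6.5,0.16,6.5,3.0,,,,,,,,
gefitinib,447,7.2,4.1,0.002,6.9,0.085,6.4,3.0,,,,2.0,5.4,15.0,,
ibrutinib,441,3.8,4.0,0.0021,6.8,0.016,7.0,3.0,,,,,,,,
ketoconazole,531,6.5,4.3,0.012,6.5,0.021,6.5,3.0,,,,,,,,
palbociclib,448,7.4,1.3,0.009,7.9,,,,,,,,,,4.5e-5,7.4
posaconazole,701,4.6,5.4,0.0001,6.5,0.005,6.5,3.0,,,,,,,,
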