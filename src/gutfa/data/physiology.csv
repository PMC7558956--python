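species,state,ara,pH_STini,TST_half_min,VST_mL,pH_SI,Cbm_mM,TSI_min,VSI_mL,PE,VE,RGI_cm,DF,RParaMW,hUWL_cm,Cpd,Rmucus_um
human,fasted,0,2.0,10,125,6.5,3.0,210,130,3,10,1.5,1.7,8.46,0.03,2.2,2.9
human,fasted,1,6.0,10,125,6.5,3.0,210,130,3,10,1.5,1.7,8.46,0.03,2.2,2.9
human,fed,0,2.7,60,250,6.0,15.0,210,156,3,10,1.5,1.7,8.46,0.03,2.2,2.9
human,fed,1,6.0,60,250,6.0,15.0,210,156,3,10,1.5,1.7,8.46,0.03,2.2,2.9
dog,fasted,0,2.0,10,50,7.0,5.0,120,19,1,10,0.5,1.7,12.9,0.03,2.2,2.9
dog,fasted,1,6.0,10,50,7.0,5.0,120,19,1,10,0.5,1.7,12.9,0.03,2.2,2.9
dog,fed,0,2.0,180,250,6.0,18.0,120,22,1,10,0.5,1.7,12.9,0.03,2.2,2.9
dog,fed,1,6.0,180,250,6.0,18.0,120,22,1,10,0.5,1.7,12.9,0.03,2.2,2.9
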