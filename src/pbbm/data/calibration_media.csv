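label,pH,total_BS_mM,TC_pct,TCDC_pct,GC_pct,GDC_pct,PC_mM,OA_mg_mL,CH_mg_mL,prandial_state,observed_solubility_mg_mL,media_set
FaSSIF@pH6.5,6.5,3,100,0,0,0,0.75,0,0,fasted,0.36,conventional
FeSSIF@pH4.8,4.8,15,100,0,0,0,3.75,0,0,fed,1.94,conventional
FaSSIF+CH+OA@pH6.5,6.5,3,100,0,0,0,0.75,0.53,0.027,fasted,0.17,oa_ch
FeSSIF+CH+OA@pH4.8,4.8,15,100,0,0,0,3.75,6.5,0.72,fed,0.52,oa_ch
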