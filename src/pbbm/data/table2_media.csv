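solution,composition,TC_pct,TCDC_pct,GC_pct,GDC_pct,total_BS_fasted_mM,total_BS_fed_mM,PC_fasted_mM,PC_fed_mM,OA_fasted_mg_mL,OA_fed_mg_mL,CH_fasted_mg_mL,CH_fed_mg_mL
1,,100,0,0,0,3,15,0,0,0,0,0,0
2,,100,0,0,0,3,15,0.75,3.75,0,0,0,0
3,,100,0,0,0,3,15,0.75,3.75,0,0,0.027,0.72
4,,100,0,0,0,3,15,0.75,3.75,0.53,6.5,0.027,0.72
5,,100,0,0,0,3,15,0.75,3.75,0.53,6.5,0,0
6,1,14.9,15.1,45.1,24.9,3,15,0,0,0,0,0,0
6,2,47.1,8.8,24.6,19.5,3,15,0,0,0,0,0,0
7,1,14.9,15.1,45.1,24.9,3,15,0.75,3.75,0,0,0,0
7,2,47.1,8.8,24.6,19.5,3,15,0.75,3.75,0,0,0,0
8,1,14.9,15.1,45.1,24.9,3,15,0.75,3.75,0,0,0.027,0.72
8,2,47.1,8.8,24.6,19.5,3,15,0.75,3.75,0,0,0.027,0.72
9,1,14.9,15.1,45.1,24.9,3,15,0.75,3.75,0.53,6.5,0.027,0.72
9,2,47.1,8.8,24.6,19.5,3,15,0.75,3.75,0.53,6.5,0.027,0.72
10,1,14.9,15.1,45.1,24.9,3,15,0.75,3.75,0.53,6.5,0,0
10,2,47.1,8.8,24.6,19.5,3,15,0.75,3.75,0.53,6.5,0,0
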