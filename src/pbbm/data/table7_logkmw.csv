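media_set,species,logk_siva,medium,pH,total_BS_mM,observed_mg_mL,predicted_mg_mL,pred_obs
conventional,neutral,1.05e-6,FaSSIF@pH6.5,6.5,3,0.36,0.65,1.81
conventional,ion,5.149,FeSSIF@pH4.8,4.8,15,1.94,1.84,0.95
oa_ch,neutral,0.019,FaSSIF+CH+OA@pH6.5,6.5,3,0.17,0.2,1.18
oa_ch,ion,4.559,FeSSIF+CH+OA@pH4.8,4.8,15,0.52,0.51,0.98
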