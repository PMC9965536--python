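metric,units,simulated,simulated_cv,observed,observed_cv,pred_obs
Cmax,ng/mL,5.98,16,8.44,12.0,0.71
AUC_0_t,ng*h/mL,87.8,41,93.3,20.4,0.94
Vss,L/kg,0.34,17,0.36,0.27,0.94
CL,L/h,1.14,41,1.04,19.7,1.10
T_half,h,17.37,37,21.7,12.6,0.80
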