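medium,pH,drug_uM,rate_nmol_cm2_h,rate_sd,mass_balance_pct,mass_balance_sd,p_exact_nm_s,p_exact_sd
DMEM,7.4,2.67,0.00,0.0,74,8.3,0.0,0.0
FaSSIF,7.4,2.67,0.031,,109,,29,
FaSSIF,6.5,2.67,0.015,0.0041,97,2.4,16,4.5
FeSSIF,7.4,2.67,0.055,,87,,67,
FeSSIF,5.8,2.67,0.021,0.0068,96,9.7,23,6.9
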