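label,prandial_state,pH,mean_ug_mL,sd_ug_mL
Sol1,fasted,6.5,105,16
Sol2,fasted,6.5,328,14
Sol3,fasted,6.5,317,7.5
Sol4,fasted,6.5,128,4
Sol6_comp1,fasted,6.5,133,15
Sol6_comp2,fasted,6.5,147,33
Sol8_comp1,fasted,6.5,342,33
Sol8_comp2,fasted,6.5,285,37
Sol9_comp1,fasted,6.5,175,47
Sol9_comp2,fasted,6.5,193,47
Sol2,fed,5,1939,67
Sol4,fed,5,403,48
Sol9_comp1,fed,5,561,58
Sol9_comp2,fed,5,599,310
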