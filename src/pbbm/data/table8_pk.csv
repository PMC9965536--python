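study,dose_mg,state,metric,observed,predicted,aafe_included
ADME,200,fed,Cmax,1.3,1.0,True
ADME,200,fed,Tmax,7,5.0,True
ADME,200,fed,AUC,41.2,28.7,True
FTIH,50,fed,Cmax,0.41,0.49,True
FTIH,50,fed,Tmax,3.8,4.57,True
FTIH,50,fed,AUC,6.3,8.4,True
FTIH,100,fed,Cmax,1.18,0.96,True
FTIH,100,fed,Tmax,4.0,4.60,True
FTIH,100,fed,AUC,17.5,16.5,True
FTIH,200,fed,Cmax,1.40,1.77,True
FTIH,200,fed,Tmax,3.8,4.62,True
FTIH,200,fed,AUC,21.5,30.5,True
FTIH,320,fed,Cmax,2.16,2.4,True
FTIH,320,fed,Tmax,4.3,4.70,True
FTIH,320,fed,AUC,32.0,41.7,True
PhaseIIa,10,fed,Cmax,0.06,0.098,True
PhaseIIa,10,fed,Tmax,4.02,4.55,True
PhaseIIa,10,fed,AUC,0.91,1.7,True
PhaseIIa,40,fed,Cmax,0.47,0.4,True
PhaseIIa,40,fed,Tmax,4.06,4.55,True
PhaseIIa,40,fed,AUC,7.46,6.8,True
PhaseIIa,80,fed,Cmax,0.75,0.78,True
PhaseIIa,80,fed,Tmax,4.58,4.5,True
PhaseIIa,80,fed,AUC,11.80,13.4,True
PhaseIIa,140,fed,Cmax,1.86,1.3,True
PhaseIIa,140,fed,Tmax,4.08,4.60,True
PhaseIIa,140,fed,AUC,29.3,23,True
PhaseIIa,200,fed,Cmax,1.86,1.8,True
PhaseIIa,200,fed,Tmax,5.48,4.6,True
PhaseIIa,200,fed,AUC,27.9,30.3,True
FoodEffect,200,moderate-fat,Cmax,1.43,1.0,True
FoodEffect,200,moderate-fat,Tmax,5.00,5.25,True
FoodEffect,200,moderate-fat,AUC,41.0,31.9,True
FoodEffect,200,high-fat,Cmax,1.08,,False
FoodEffect,200,high-fat,Tmax,5.00,,False
FoodEffect,200,high-fat,AUC,36.9,,False
FoodEffect,200,fasted,Cmax,0.35,0.36,True
FoodEffect,200,fasted,Tmax,4.0,4.53,True
FoodEffect,200,fasted,AUC,13.5,10.9,True
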