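risk_factor,value,se,unit_label,distribution
bmi,21,1,kg/m2,normal
sbp,115,6,mmHg,normal
cholesterol,3.8,0.6,mmol/L,normal
vegetables,400,30,g/day,normal
fruit,300,30,g/day,normal
fibre,30,3,g/day,normal
red_meat,14.3,1.43,g/day,normal
processed_meat,0,0,g/day,normal
physical_activity,133,13.3,METhr/wk,normal
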