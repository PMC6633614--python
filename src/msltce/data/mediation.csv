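disease,exposure,intermediate,unit_value,unit_label,coefficient,se,distribution
stroke,bmi,sbp,1,kg/m2,0.65,0.04,normal
stroke,fruit,sbp,80,g/day,0.42,0.17,normal
stroke,vegetables,sbp,80,g/day,0.54,0.2,normal
stroke,fruit,cholesterol,80,g/day,0.027,0.017,normal
stroke,vegetables,cholesterol,80,g/day,0.047,0.026,normal
ihd,bmi,sbp,1,kg/m2,0.31,0.016,normal
ihd,fruit,sbp,80,g/day,0.39,0.15,normal
ihd,vegetables,sbp,80,g/day,0.47,0.21,normal
ihd,fruit,cholesterol,80,g/day,0.008,0.0057,normal
ihd,vegetables,cholesterol,80,g/day,0.012,0.01,normal
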