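risk_factor,intermediate,unit_value,unit_label,coefficient,se,distribution,notes
total_fat,cholesterol,1,%energy,0.020,0.005,normal,
saturated_fat,cholesterol,1,%energy,0.052,0.003,normal,
mufa,cholesterol,1,%energy,0.005,0.003,normal,
pufa,cholesterol,1,%energy,-0.026,0.004,normal,
dietary_cholesterol,cholesterol,1,g/day,0.0007,0.0001,normal,
salt,sbp,100,mmol Na/24h,5.80,1.71,normal,grams of salt consumed per day converted to urinary sodium excretion
total_energy,bmi,1,kJ/day,,,normal,external steady-state energy-balance relation; replaced by configurable linear coefficient (see EnergyBalanceConfig)
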