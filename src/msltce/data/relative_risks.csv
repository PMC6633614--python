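risk_factor,disease,sex,age_band,exposure_band,unit_value,unit_label,value,se,distribution,form
fruit,ihd,,,,106,g/day,0.93,0.019,lognormal,rr_per_unit
fruit,stroke,,,,106,g/day,0.89,0.023,lognormal,rr_per_unit
fruit,lung_cancer,,,,100,g/day,0.94,0.02,lognormal,rr_per_unit
vegetables,ihd,,,,106,g/day,0.89,0.034,lognormal,rr_per_unit
vegetables,lung_cancer,,,,100,g/day,0.94,0.025,lognormal,rr_per_unit
fibre_cereal,ihd,,,,10,g/day,0.91,0.02,lognormal,rr_per_unit
fibre,breast_cancer,,,,10,g/day,0.93,0.027,lognormal,rr_per_unit
fibre,colorectal_cancer,,,,10,g/day,0.90,0.034,lognormal,rr_per_unit
fibre,stomach_cancer,,,,10,g/day,0.56,0.12,lognormal,rr_per_unit
red_meat,colorectal_cancer,,,,100,g/day,1.30,0.06,lognormal,rr_per_unit
red_meat,stomach_cancer,,,,100,g/day,1.13,0.036,lognormal,rr_per_unit
red_meat,diabetes,,,,100,g/day,1.20,0.072,lognormal,rr_per_unit
processed_meat,colorectal_cancer,,,,50,g/day,1.38,0.07,lognormal,rr_per_unit
processed_meat,diabetes,,,,50,g/day,1.57,0.1,lognormal,rr_per_unit
cholesterol,ihd,,<49,,-1,mmol/L,0.44,0.034,lognormal,rr_per_unit
cholesterol,ihd,,50-59,,-1,mmol/L,0.58,0.034,lognormal,rr_per_unit
cholesterol,ihd,,60-69,,-1,mmol/L,0.72,0.018,lognormal,rr_per_unit
cholesterol,ihd,,70-79,,-1,mmol/L,0.82,0.015,lognormal,rr_per_unit
cholesterol,ihd,,80+,,-1,mmol/L,0.85,0.21,lognormal,rr_per_unit
cholesterol,stroke,,<59,,-1,mmol/L,0.90,0.037,lognormal,rr_per_unit
cholesterol,stroke,,60-69,,-1,mmol/L,1.02,0.027,lognormal,rr_per_unit
cholesterol,stroke,,70-79,,-1,mmol/L,1.04,0.025,lognormal,rr_per_unit
cholesterol,stroke,,80+,,-1,mmol/L,1.06,0.031,lognormal,rr_per_unit
sbp,ihd,,<49,,-20,mmHg,0.49,0.042,lognormal,rr_per_unit
sbp,ihd,,50-59,,-20,mmHg,0.50,0.015,lognormal,rr_per_unit
sbp,ihd,,60-69,,-20,mmHg,0.54,0.0094,lognormal,rr_per_unit
sbp,ihd,,70-79,,-20,mmHg,0.60,0.013,lognormal,rr_per_unit
sbp,ihd,,80+,,-20,mmHg,0.67,0.023,lognormal,rr_per_unit
sbp,stroke,,<49,,-20,mmHg,0.36,0.057,lognormal,rr_per_unit
sbp,stroke,,50-59,,-20,mmHg,0.38,0.034,lognormal,rr_per_unit
sbp,stroke,,60-69,,-20,mmHg,0.43,0.024,lognormal,rr_per_unit
sbp,stroke,,70-79,,-20,mmHg,0.50,0.02,lognormal,rr_per_unit
sbp,stroke,,80+,,-20,mmHg,0.67,0.03,lognormal,rr_per_unit
bmi,ihd,,35-59,,5,kg/m2,1.50,0.039,lognormal,rr_per_unit
bmi,ihd,,60-69,,5,kg/m2,1.40,0.031,lognormal,rr_per_unit
bmi,ihd,,70-79,,5,kg/m2,1.31,0.033,lognormal,rr_per_unit
bmi,ihd,,80-89,,5,kg/m2,1.30,0.055,lognormal,rr_per_unit
bmi,stroke,,35-59,,5,kg/m2,1.76,0.075,lognormal,rr_per_unit
bmi,stroke,,60-69,,5,kg/m2,1.49,0.056,lognormal,rr_per_unit
bmi,stroke,,70-79,,5,kg/m2,1.33,0.056,lognormal,rr_per_unit
bmi,stroke,,80-89,,5,kg/m2,1.10,0.083,lognormal,rr_per_unit
bmi,diabetes,,,15-25,5,kg/m2,0.96,0.25,lognormal,rr_per_unit
bmi,diabetes,,,25-50,5,kg/m2,2.16,0.067,lognormal,rr_per_unit
bmi,pancreatic_cancer,,,,5,kg/m2,1.10,0.016,lognormal,rr_per_unit
bmi,colorectal_cancer,male,,,5,kg/m2,1.24,0.016,lognormal,rr_per_unit
bmi,colorectal_cancer,female,,,5,kg/m2,1.09,0.019,lognormal,rr_per_unit
bmi,breast_cancer,female,60+,,5,kg/m2,1.12,0.018,lognormal,rr_per_unit
bmi,kidney_cancer,male,,,5,kg/m2,1.24,0.039,lognormal,rr_per_unit
bmi,kidney_cancer,female,,,5,kg/m2,1.34,0.034,lognormal,rr_per_unit
bmi,liver_cancer,,,,5,kg/m2,1.47,0.078,lognormal,rr_per_unit
bmi,liver_cirrhosis,,,15-25,5,kg/m2,0.73,0.016,lognormal,rr_per_unit
bmi,liver_cirrhosis,,,25-50,5,kg/m2,1.79,0.077,lognormal,rr_per_unit
diabetes,ihd,male,,,,prevalence,1.85,0.063,lognormal,rr_binary
diabetes,ihd,female,,,,prevalence,2.63,0.076,lognormal,rr_binary
diabetes,stroke,male,,,,prevalence,1.83,0.067,lognormal,rr_binary
diabetes,stroke,female,,,,prevalence,2.28,0.085,lognormal,rr_binary
physical_activity,ihd,,,,11.25,METhr/wk,-0.204,0.027,normal,beta_quarter_power
physical_activity,stroke,,,,11.25,METhr/wk,-0.195,0.041,normal,beta_quarter_power
physical_activity,diabetes,,,,11.25,METhr/wk,-0.240,0.023,normal,beta_quarter_power
physical_activity,colorectal_cancer,,,,11.25,METhr/wk,-0.080,0.059,normal,beta_quarter_power
physical_activity,breast_cancer,,,,11.25,METhr/wk,-0.053,0.023,normal,beta_quarter_power
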