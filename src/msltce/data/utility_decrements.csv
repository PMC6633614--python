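disease,phase,value,se
ihd,incident,-0.071,0.024
ihd,prevalent,-0.070,0.015
stroke,incident,-0.094,0.019
stroke,prevalent,-0.046,0.031
diabetes,all,-0.071,0.005
breast_cancer,all,-0.019,0.014
colorectal_cancer,all,-0.067,0.017
lung_cancer,all,-0.119,0.043
stomach_cancer,all,-0.071,0.105
liver_cancer,all,-0.093,0.044
kidney_cancer,all,-0.048,0.041
pancreatic_cancer,all,-0.086,0.027
liver_cirrhosis,all,-0.083,0.031
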