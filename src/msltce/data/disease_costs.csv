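disease,pb_category,programme_budgeting_k,specialised_services_k,primary_care_k,total_k,cost_per_prevalent_case
ihd,10a Coronary Heart Disease,953743,41818,485056,1480617,1905
stroke,10b Cerebrovascular disease,689876,55443,29475,774794,843
diabetes,04a Diabetes,1071537,25577,959716,2056831,444
breast_cancer,02f Cancer breast,472192,,,472192,573
colorectal_cancer,02c Cancer lower GI,248315,84919,20,333253,810
lung_cancer,02d Cancer lung,98250,33599,0,131849,904
stomach_cancer,02b Cancer upper GI,32794,11215,0,44008,535
liver_cancer,02b Cancer upper GI,16990,5810,0,22801,1532
kidney_cancer,02h Cancer urological,25145,8599,7833,41577,618
pancreatic_cancer,02b Cancer upper GI,42133,14409,0,56542,3074
liver_cirrhosis,13c Hepatobiliary,59702,4543,2963,67209,314
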