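disease,name,sexes,annual_cost,utility_male,utility_female
chd,Coronary heart disease,both,2838.70,0.76,0.76
stroke,Stroke,both,1627.26,0.713,0.713
hypertension,Hypertension,both,493.15,0.721,0.721
t2dm,Type 2 diabetes mellitus,both,672.28,0.661,0.661
knee_osteoarthritis,Knee osteoarthritis,both,223.97,0.49,0.46
breast_cancer,Breast cancer,female_only,13295.53,,0.749
colorectal_cancer,Colorectal cancer,both,13563.22,0.676,0.676
endometrial_cancer,Endometrial cancer,female_only,2471.21,,0.598
oesophageal_cancer,Oesophageal cancer,both,9568.28,0.904,0.904
ovarian_cancer,Ovarian cancer,female_only,1408.94,,0.848
pancreatic_cancer,Pancreatic cancer,both,5735.93,0.79,0.79
renal_cancer,Renal cancer,both,414.81,0.661,0.661
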