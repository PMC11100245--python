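factor,category,count
total,cohort,5375
sex,Female,3515
sex,Male,1486
sex,Unknown,374
age,<18,307
age,18-45,940
age,45-65,1065
age,65-75,328
age,>=75,163
age,Unknown,2572
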