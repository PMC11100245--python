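table,soc,pt,a,ror,ror_lo,ror_hi,prr,prr_lo,prr_hi,chi2,ic,ic025,ebgm,ebgm05
by_count,Injury poisoning and procedural complications,Off label use,929,4.73,4.42,5.05,4.49,4.22,4.78,2555.15,2.16,2.06,4.49,4.20
by_count,Gastrointestinal disorders,Diarrhoea,633,4.19,3.87,4.54,4.05,3.76,4.38,1470.19,2.01,1.89,4.05,3.74
by_count,Gastrointestinal disorders,Nausea,514,2.83,2.59,3.09,2.77,2.54,3.01,586.24,1.46,1.33,2.76,2.53
by_count,Psychiatric disorders,Insomnia,505,8.17,7.48,8.93,7.93,7.27,8.64,3061.21,2.96,2.83,7.91,7.23
by_count,Psychiatric disorders,Anxiety,365,5.32,4.79,5.90,5.21,4.71,5.77,1245.05,2.36,2.21,5.20,4.69
by_count,Nervous system disorders,Dizziness,310,2.67,2.39,2.99,2.64,2.36,2.94,317.29,1.39,1.23,2.64,2.36
by_count,Nervous system disorders,Paraesthesia,266,7.06,6.26,7.98,6.96,6.17,7.84,1356.55,2.76,2.58,6.94,6.15
by_count,General disorders and administration site conditions,Feeling abnormal,259,4.28,3.78,4.83,4.22,3.74,4.76,637.54,2.06,1.88,4.21,3.73
by_count,Psychiatric disorders,Suicidal ideation,248,12.71,11.20,14.41,12.51,11.06,14.16,2618.68,3.57,3.39,12.46,10.99
by_count,Psychiatric disorders,Depression,243,4.63,4.08,5.25,4.57,4.03,5.17,678.51,2.17,1.98,4.56,4.02
by_count,Psychiatric disorders,Hallucination,172,10.73,9.23,12.47,10.61,9.15,12.32,1493.91,3.33,3.10,10.58,9.10
by_count,Psychiatric disorders,Agitation,164,10.13,8.69,11.82,10.03,8.61,11.69,1330.55,3.25,3.02,10.00,8.57
by_count,Nervous system disorders,Tremor,151,3.93,3.35,4.61,3.90,3.33,4.57,325.95,1.93,1.70,3.90,3.32
by_count,Investigations,Weight increased,142,2.76,2.34,3.26,2.74,2.33,3.23,157.59,1.44,1.19,2.74,2.32
both,Psychiatric disorders,Abnormal dreams,141,25.33,21.45,29.93,25.10,21.28,29.61,3236.04,4.41,4.17,24.89,21.07
by_count,Nervous system disorders,Somnolence,140,2.99,2.53,3.53,2.97,2.52,3.50,183.32,1.55,1.31,2.97,2.51
both,Psychiatric disorders,Nightmare,137,17.86,15.09,21.14,17.71,14.98,20.93,2147.30,3.97,3.73,17.60,14.87
by_count,Psychiatric disorders,Irritability,131,9.23,7.77,10.97,9.16,7.72,10.86,949.90,3.10,2.85,9.13,7.69
both,General disorders and administration site conditions,Crying,121,14.49,12.11,17.34,14.38,12.04,17.18,1499.70,3.69,3.43,14.31,11.96
by_count,Cardiac disorders,Palpitations,108,3.97,3.28,4.80,3.95,3.27,4.76,237.79,1.94,1.66,3.94,3.26
by_count,Skin and subcutaneous tissue disorders,Hyperhidrosis,104,3.46,2.85,4.20,3.44,2.84,4.17,180.50,1.75,1.47,3.44,2.84
by_count,Psychiatric disorders,Confusional state,104,2.80,2.31,3.40,2.79,2.30,3.38,119.47,1.45,1.17,2.79,2.30
by_count,Psychiatric disorders,Anger,97,12.50,10.23,15.27,12.42,10.18,15.15,1014.91,3.47,3.18,12.37,10.13
by_count,Psychiatric disorders,Panic attack,88,10.68,8.65,13.17,10.62,8.62,13.08,764.36,3.26,2.95,10.58,8.58
by_count,Eye disorders,Vision blurred,85,2.73,2.20,3.37,2.72,2.20,3.36,92.25,1.41,1.10,2.71,2.19
both,Nervous system disorders,Serotonin syndrome,81,19.96,16.04,24.86,19.86,15.97,24.70,1441.26,4.01,3.68,19.73,15.85
both,Psychiatric disorders,Mania,77,21.90,17.49,27.41,21.79,17.42,27.25,1516.03,4.10,3.77,21.63,17.28
by_count,Psychiatric disorders,Aggression,69,6.52,5.15,8.27,6.50,5.13,8.22,320.45,2.59,2.24,6.49,5.12
by_count,Musculoskeletal and connective tissue disorders,Muscle twitching,61,11.43,8.88,14.70,11.38,8.86,14.63,575.68,3.28,2.91,11.34,8.82
both,General disorders and administration site conditions,Feeling jittery,58,13.43,10.37,17.40,13.38,10.35,17.32,661.77,3.46,3.09,13.33,10.29
by_ebgm,Nervous system disorders,Sleep paralysis,55,157.34,119.89,206.50,156.76,119.56,205.54,8072.54,5.35,4.96,148.71,113.31
by_ebgm,Psychiatric disorders,Hypnagogic hallucination,8,118.66,58.50,240.70,118.59,58.49,240.48,895.88,3.07,2.09,113.94,56.17
by_ebgm,Psychiatric disorders,Female orgasmic disorder,4,54.28,20.18,145.97,54.26,20.18,145.90,205.25,2.22,0.91,53.28,19.81
by_ebgm,Psychiatric disorders,Rapid eye movements sleep abnormal,5,51.56,21.29,124.86,51.54,21.29,124.78,243.43,2.45,1.26,50.65,20.91
by_ebgm,Injury poisoning and procedural complications,Discontinued product administered,3,46.90,14.99,146.78,46.89,14.99,146.71,132.57,1.91,0.45,46.15,14.75
by_ebgm,Nervous system disorders,Cold-stimulus headache,3,37.52,12.01,117.21,37.51,12.01,117.16,105.24,1.89,0.43,37.04,11.86
by_ebgm,Psychiatric disorders,Sleep terror,33,34.97,24.80,49.31,34.89,24.76,49.16,1073.41,4.12,3.62,34.49,24.46
by_ebgm,Psychiatric disorders,Orgasm abnormal,6,34.46,15.40,77.07,34.44,15.40,77.02,192.52,2.57,1.47,34.05,15.22
by_ebgm,Nervous system disorders,Electric shock sensation,15,33.68,20.24,56.05,33.65,20.23,55.97,469.71,3.46,2.74,33.27,19.99
by_ebgm,Psychiatric disorders,Violence-related symptom,10,28.72,15.40,53.55,28.70,15.40,53.50,264.73,3.02,2.15,28.43,15.25
by_ebgm,Psychiatric disorders,Terminal insomnia,9,26.95,13.98,51.96,26.93,13.97,51.91,222.66,2.90,1.98,26.69,13.84
by_ebgm,Psychiatric disorders,Tachyphrenia,23,25.89,17.17,39.04,25.85,17.15,38.96,544.54,3.66,3.07,25.63,16.99
by_ebgm,Injury poisoning and procedural complications,Gun shot wound,7,25.66,12.19,54.01,25.64,12.19,53.96,164.33,2.65,1.62,25.43,12.08
by_ebgm,Reproductive system and breast disorders,Ejaculation delayed,3,22.89,7.35,71.30,22.89,7.35,71.27,62.29,1.82,0.37,22.71,7.29
by_ebgm,Psychiatric disorders,Disturbance in sexual arousal,5,22.23,9.22,53.60,22.22,9.22,53.57,100.57,2.29,1.11,22.06,9.15
by_ebgm,Reproductive system and breast disorders,Spontaneous penile erection,3,21.90,7.03,68.21,21.90,7.03,68.18,59.38,1.81,0.36,21.74,6.98
by_ebgm,Psychiatric disorders,Morbid thoughts,5,21.25,8.81,51.22,21.24,8.81,51.19,95.73,2.28,1.09,21.09,8.75
by_ebgm,Psychiatric disorders,Anorgasmia,12,20.67,11.71,36.48,20.65,11.71,36.43,222.82,3.04,2.23,20.51,11.62
by_ebgm,Psychiatric disorders,Hypomania,16,19.60,11.98,32.06,19.58,11.98,32.01,280.21,3.22,2.52,19.45,11.90
by_ebgm,Injury poisoning and procedural complications,Drug dose titration not performed,8,18.30,9.13,36.68,18.29,9.13,36.64,129.92,2.64,1.68,18.18,9.07
by_ebgm,Reproductive system and breast disorders,Sexual dysfunction,47,17.62,13.22,23.49,17.57,13.20,23.39,730.15,3.70,3.28,17.47,13.11
by_ebgm,Psychiatric disorders,Hostility,8,15.83,7.90,31.72,15.82,7.90,31.70,110.49,2.58,1.61,15.74,7.86
by_ebgm,Psychiatric disorders,Obsessive thoughts,5,13.41,5.57,32.28,13.40,5.57,32.26,57.11,2.13,0.94,13.34,5.54
by_ebgm,Injury poisoning and procedural complications,Drug titration error,8,12.77,6.38,25.59,12.77,6.38,25.57,86.39,2.47,1.50,12.72,6.35
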