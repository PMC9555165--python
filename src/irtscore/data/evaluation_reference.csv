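method,quantity,none,mild,moderate,severe,overall,d01,d02,d03,d12,d13,d23
groups,n,302,31,14,8,,,,,,,
unweighted,mean,1.37,6.52,15.76,32.25,,,,,,,
unweighted,se,0.16,0.93,4.41,3.74,,,,,,,
unweighted,mean_diff,,,,,,5.15,14.39,30.88,9.24,25.73,16.49
unweighted,F,,,,,164.82,35.64,133.24,356.25,80.35,190.88,237.65
unweighted,RP,,,,,1.000,1.000,1.000,1.000,1.000,1.000,1.000
frequency,mean,0.95,4.00,8.43,14.00,,,,,,,
frequency,se,0.10,0.43,1.55,1.55,,,,,,,
frequency,mean_diff,,,,,,3.05,7.48,13.05,4.43,10.00,5.57
frequency,F,,,,,162.04,58.47,167.32,296.78,106.98,171.58,224.77
frequency,RP,,,,,0.983,1.641,1.256,0.833,1.331,0.899,0.946
grm,mean,3.00,14.33,30.63,48.09,,,,,,,
grm,se,0.32,1.69,4.54,5.04,,,,,,,
grm,mean_diff,,,,,,11.33,27.63,45.09,16.30,33.76,17.46
grm,F,,,,,187.95,73.92,209.17,324.53,134.11,192.09,258.34
grm,RP,,,,,1.140,2.074,1.570,0.911,1.669,1.006,1.087
grm_dif,mean,3.07,14.58,31.50,48.32,,,,,,,
grm_dif,se,0.32,1.67,4.59,4.79,,,,,,,
grm_dif,mean_diff,,,,,,11.51,28.43,45.25,16.92,33.74,16.82
grm_dif,F,,,,,192.35,75.94,220.57,325.57,140.52,193.51,264.31
grm_dif,RP,,,,,1.167,2.131,1.655,0.914,1.749,1.014,1.112
nrm,mean,2.22,10.35,21.20,35.09,,,,,,,
nrm,se,0.22,1.29,3.51,4.51,,,,,,,
nrm,mean_diff,,,,,,8.13,18.98,32.87,10.85,24.74,13.89
nrm,F,,,,,172.23,68.40,177.61,310.47,116.41,182.73,236.37
nrm,RP,,,,,1.045,1.919,1.333,0.871,1.449,0.957,0.995
nrm_dif,mean,2.42,11.07,22.57,38.24,,,,,,,
nrm_dif,se,0.25,1.35,3.99,4.94,,,,,,,
nrm_dif,mean_diff,,,,,,8.65,20.15,35.82,11.50,27.17,15.67
nrm_dif,F,,,,,164.76,63.82,164.73,303.34,108.14,177.18,226.74
nrm_dif,RP,,,,,1.000,1.791,1.236,0.851,1.346,0.928,0.954
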