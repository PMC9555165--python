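set,item,name,group,a,b1,b2,b3,b4,b5,b6
pooled,1,Mood,all,4.043,1.111,1.510,1.926,1.998,2.263,2.534
pooled,2,Interest,all,3.182,0.766,1.464,2.059,2.183,2.504,2.758
pooled,3,Sleep,all,1.284,1.137,1.894,2.475,2.655,2.997,3.525
pooled,4,Fatigue,all,3.004,1.303,1.774,2.303,2.436,2.670,2.990
pooled,5,Weight,all,1.425,1.461,2.013,2.702,2.972,3.351,3.776
pooled,6,Guilty,all,2.191,1.399,1.876,2.320,2.513,2.820,3.187
pooled,7,Concentration,all,2.176,1.028,1.835,2.462,2.556,3.004,3.406
pooled,8,Psychomotor,all,2.063,1.202,1.830,2.443,2.535,2.912,3.376
pooled,9,Suicide,all,2.997,1.979,2.296,2.605,2.819,3.001,3.290
dif,1,Mood,all,3.834,1.189,1.581,1.986,2.056,2.311,2.570
dif,2,Interest,male,2.160,1.055,1.796,2.705,2.806,2.920,3.467
dif,2,Interest,female,2.160,0.869,1.698,2.302,2.456,2.917,3.114
dif,3,Sleep,all,1.361,1.173,1.894,2.446,2.618,2.943,3.443
dif,4,Fatigue,all,3.072,1.360,1.820,2.333,2.578,2.929,3.115
dif,5,Weight,male,2.160,1.259,1.675,1.932,2.113,2.442,2.805
dif,5,Weight,female,2.160,1.289,1.706,2.391,2.612,2.827,3.075
dif,6,Guilty,all,2.265,1.446,1.909,2.341,2.527,2.823,3.176
dif,7,Concentration,all,2.304,1.077,1.853,2.453,2.542,2.967,3.350
dif,8,Psychomotor,all,2.194,1.242,1.843,2.427,2.513,2.871,3.311
dif,9,Suicide,all,3.176,1.998,2.305,2.603,2.809,3.051,3.285
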