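set,item,name,group,param,v11,v12,v13,v21,v22,v23,v31,v32,v33,f11,f12,f13,f21,f22,f23,f31,f32,f33
pooled,1,Mood,all,a,2.817,4.147,5.575,5.899,8.204,10.329,5.391,17.461,18.590,0,0,0,0,0,0,0,0,0
pooled,1,Mood,all,c,1.396,2.056,2.074,1.429,1.602,1.745,1.839,1.828,1.792,0,0,0,0,0,0,0,0,0
pooled,2,Interest,all,a,2.817,5.102,8.882,4.095,7.303,8.797,11.209,11.209,12.589,0,0,0,0,0,0,0,1,0
pooled,2,Interest,all,c,0.896,1.713,1.710,1.180,1.499,1.630,1.730,1.730,1.702,0,0,0,0,0,0,0,1,0
pooled,3,Sleep,all,a,0.726,1.471,1.227,1.318,2.100,1.355,2.267,2.794,2.394,0,0,0,0,0,0,0,0,0
pooled,3,Sleep,all,c,2.657,3.758,4.077,2.369,2.335,3.199,2.822,2.746,2.124,0,0,0,0,0,0,0,0,0
pooled,4,Fatigue,all,a,1.806,6.653,12.413,3.545,11.530,8.426,16.246,21.364,20.098,0,0,0,0,0,0,0,0,0
pooled,4,Fatigue,all,c,1.866,2.001,1.963,1.727,1.856,1.891,1.953,2.086,1.960,0,0,0,0,0,0,0,0,0
pooled,5,Weight,all,a,1.264,-0.987,2.110,1.584,1.757,1.573,1.237,1.879,2.199,0,0,0,0,0,0,0,0,0
pooled,5,Weight,all,c,2.214,-6.726,2.724,2.152,2.829,3.351,4.594,4.082,2.535,0,0,0,0,0,0,0,0,0
pooled,6,Guilty,all,a,1.543,3.078,0.661,2.215,4.392,3.194,3.097,3.373,6.390,0,0,0,0,0,0,0,0,0
pooled,6,Guilty,all,c,2.070,2.444,9.259,2.111,2.035,2.568,2.329,2.426,2.050,0,0,0,0,0,0,0,0,0
pooled,7,Concentration,all,a,1.457,3.504,3.640,2.947,4.583,6.095,5.375,5.761,6.831,0,0,0,0,0,0,0,0,0
pooled,7,Concentration,all,c,1.485,2.449,2.412,1.630,1.832,2.254,2.170,1.992,1.974,0,0,0,0,0,0,0,0,0
pooled,8,Psychomotor,all,a,1.544,4.594,4.594,2.213,3.027,4.682,3.270,2.832,5.722,0,0,1,0,0,0,0,0,0
pooled,8,Psychomotor,all,c,1.711,2.335,2.335,1.844,2.109,2.130,2.396,2.649,2.047,0,0,1,0,0,0,0,0,0
pooled,9,Suicide,all,a,3.006,22.604,22.604,3.784,5.533,8.547,7.059,5.426,7.316,0,0,1,0,0,0,0,0,0
pooled,9,Suicide,all,c,2.164,2.644,2.644,2.212,2.294,2.348,2.157,2.377,2.225,0,0,1,0,0,0,0,0,0
dif,1,Mood,male,a,1.877,3.535,4.823,7.482,7.182,9.688,2.965,16.850,18.626,0,1,1,0,0,0,0,0,0
dif,1,Mood,male,c,1.850,2.170,2.177,1.544,1.763,1.720,2.242,1.887,1.942,0,1,1,0,0,0,0,0,0
dif,1,Mood,female,a,1.877,3.535,4.823,4.416,7.203,6.588,8.015,10.973,12.933,0,0,0,0,0,0,0,0,0
dif,1,Mood,female,c,1.680,2.170,2.177,1.498,1.636,2.001,1.854,1.845,1.751,0,0,0,0,0,0,0,0,0
dif,2,Interest,male,a,1.877,5.161,8.094,3.785,6.309,5.527,11.454,11.454,15.614,0,1,1,0,0,0,0,1,0
dif,2,Interest,male,c,1.305,1.747,1.730,1.354,1.929,1.753,1.989,1.989,2.071,0,0,1,1,0,0,0,1,0
dif,2,Interest,female,a,1.877,5.161,8.094,2.835,6.749,9.965,11.361,11.361,11.784,0,0,0,0,0,0,0,1,0
dif,2,Interest,female,c,1.014,1.747,1.730,1.376,1.536,1.746,1.774,1.774,1.703,0,0,0,0,0,0,0,1,0
dif,3,Sleep,all,a,0.770,1.500,1.292,1.402,2.153,1.443,2.194,2.290,3.057,0,0,0,0,0,0,0,0,0
dif,3,Sleep,all,c,2.531,3.705,3.913,2.282,2.307,3.059,2.787,2.458,2.009,0,0,0,0,0,0,0,0,0
dif,4,Fatigue,male,a,1.877,7.178,10.268,4.539,10.076,6.696,12.374,17.574,10.240,0,0,1,0,1,0,1,0,0
dif,4,Fatigue,male,c,1.941,2.006,1.921,1.650,1.797,1.851,1.895,2.262,1.909,0,0,1,0,1,0,1,0,0
dif,4,Fatigue,female,a,1.877,6.386,10.268,3.231,10.076,9.269,12.374,17.574,15.687,0,0,0,0,0,0,0,1,0
dif,4,Fatigue,female,c,1.803,2.005,1.921,1.776,1.797,1.927,1.895,2.262,1.943,0,0,0,0,0,0,0,1,0
dif,5,Weight,male,a,1.877,-0.121,2.490,2.534,1.595,1.163,2.794,2.218,2.045,0,0,0,0,0,0,0,1,0
dif,5,Weight,male,c,1.758,-46.399,2.394,1.939,2.513,3.596,2.283,3.409,2.399,0,0,0,0,0,0,0,1,0
dif,5,Weight,female,a,1.877,-4.018,2.619,1.651,3.144,3.148,-3.384,2.218,3.146,0,0,0,0,0,0,0,0,0
dif,5,Weight,female,c,1.726,-3.104,2.392,1.955,2.292,2.454,-3.221,3.409,2.185,0,0,0,0,0,0,0,0,0
dif,6,Guilty,all,a,1.523,3.194,0.821,2.319,4.138,2.853,3.147,3.791,6.204,0,0,0,0,0,0,0,0,0
dif,6,Guilty,all,c,2.101,2.412,7.557,2.077,2.056,2.710,2.319,2.334,2.063,0,0,0,0,0,0,0,0,0
dif,7,Concentration,male,a,1.877,4.159,4.698,5.225,5.786,6.666,6.649,6.759,13.936,0,1,0,0,0,1,0,0,0
dif,7,Concentration,male,c,1.312,2.150,1.856,1.469,1.815,2.085,1.921,1.818,2.223,0,1,0,0,0,1,0,0,0
dif,7,Concentration,female,a,1.877,4.159,4.698,2.834,5.097,6.666,7.160,7.134,7.604,0,0,1,0,0,0,0,0,0
dif,7,Concentration,female,c,1.283,2.150,1.856,1.603,1.708,2.085,2.077,1.923,1.865,0,0,1,0,0,0,0,0,0
dif,8,Psychomotor,male,a,1.877,4.798,4.798,2.925,1.882,7.366,9.494,6.674,10.526,0,1,1,0,0,0,0,0,0
dif,8,Psychomotor,male,c,1.440,2.200,2.200,1.560,2.912,1.744,1.996,1.967,1.972,0,1,1,0,0,0,0,0,0
dif,8,Psychomotor,female,a,1.877,4.798,4.798,2.384,3.708,7.366,2.877,2.164,6.045,0,0,1,0,0,1,0,0,0
dif,8,Psychomotor,female,c,1.582,2.200,2.200,1.796,1.920,1.744,2.486,3.105,2.003,0,0,1,0,0,1,0,0,0
dif,9,Suicide,male,a,1.877,11.826,11.826,4.163,4.929,9.665,9.195,4.550,18.334,0,1,1,0,1,0,0,1,0
dif,9,Suicide,male,c,2.759,2.517,2.517,2.101,2.328,2.181,2.062,2.454,2.390,0,1,1,0,1,0,0,1,0
dif,9,Suicide,female,a,1.877,11.826,11.826,3.119,4.929,9.665,5.990,4.550,3.777,0,0,1,0,0,1,0,0,0
dif,9,Suicide,female,c,2.684,2.517,2.517,2.439,2.328,2.181,2.337,2.454,2.591,0,0,1,0,0,1,0,0,0
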