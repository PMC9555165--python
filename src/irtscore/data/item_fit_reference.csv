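coding,item,name,chi2,p_text
product,1,Mood,25.57,<0.001
product,2,Interest,1.75,0.186
product,3,Sleep,7.57,0.006
product,4,Fatigue,4.90,0.027
product,5,Weight,5.98,0.015
product,6,Guilty,1.37,0.241
product,7,Concentration,4.76,0.029
product,8,Psychomotor,3.07,0.080
product,9,Suicide,22.79,<0.001
combination,1,Mood,39.37,<0.001
combination,2,Interest,6.48,0.011
combination,3,Sleep,9.28,0.002
combination,4,Fatigue,4.49,0.034
combination,5,Weight,10.46,0.001
combination,6,Guilty,7.07,0.008
combination,7,Concentration,9.96,0.002
combination,8,Psychomotor,3.21,0.073
combination,9,Suicide,45.38,<0.001
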