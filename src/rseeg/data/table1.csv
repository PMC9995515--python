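measure,test,group,mean,sd,n
age,anova,never,53.09,4.96,33
age,anova,past,54.64,6.48,28
age,anova,smoker,56.30,7.12,20
income,anova,never,3.15,1.25,33
income,anova,past,3.14,1.41,28
income,anova,smoker,2.85,1.42,20
kbdi,anova,never,8.63,6.89,33
kbdi,anova,past,9.96,6.50,28
kbdi,anova,smoker,8.75,6.27,20
initiation_age,t,past,19.43,1.32,28
initiation_age,t,smoker,18.10,1.80,20
years_smoking,t,past,10.21,6.43,28
years_smoking,t,smoker,37.80,7.54,20
cigarettes_per_day,t,past,18.24,9.05,21
cigarettes_per_day,t,smoker,20.53,6.76,19
ftnd,t,past,3.15,3.17,20
ftnd,t,smoker,5.58,2.09,19
qsu,t,past,10.80,2.73,20
qsu,t,smoker,21.32,10.17,19
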