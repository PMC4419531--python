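variable,group1,mean1,sd1,n1,group2,mean2,sd2,n2
Age,spd,20.08,1.04,25,non_spd,20.04,1.31,25
Education,spd,13.76,0.97,25,non_spd,12.84,0.85,25
IQ estimates,spd,126.61,10.65,25,non_spd,126.71,9.36,25
SPQ_Cognitive perception,spd,17.88,5.39,25,non_spd,4.64,3.13,25
SPQ_Interpersonal,spd,12.44,4.18,25,non_spd,2.60,1.94,25
SPQ_Disorganization,spd,9.36,2.14,25,non_spd,1.84,2.04,25
SPQ_Total score,spd,40.84,6.61,25,non_spd,9.16,5.06,25
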