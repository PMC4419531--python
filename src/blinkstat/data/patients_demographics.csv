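variable,group1,mean1,sd1,n1,group2,mean2,sd2,n2
Age,schizophrenia,27.04,7.35,24,control,28.08,6.51,24
Education,schizophrenia,10.25,3.18,24,control,10.79,2.86,24
IQ estimates,schizophrenia,90.29,21.86,24,control,104.50,10.55,24
Logic memory (in time),schizophrenia,7.29,4.95,24,control,13.04,4.55,24
Logic memory (delayed),schizophrenia,5.50,4.66,24,control,10.96,5.23,24
Visual memory (in time),schizophrenia,18.79,3.64,24,control,20.58,3.32,24
Visual memory (delayed),schizophrenia,18.13,4.01,24,control,20.29,3.57,24
0-back ACC,schizophrenia,0.88,0.19,24,control,0.95,0.10,24
0-back RT,schizophrenia,621.51,130.80,24,control,537.19,141.22,24
1-back ACC,schizophrenia,0.32,0.23,24,control,0.53,0.29,24
1-back RT,schizophrenia,765.71,280.60,24,control,751.18,246.55,24
2-back ACC,schizophrenia,0.19,0.14,24,control,0.36,0.22,24
2-back RT,schizophrenia,652.33,206.96,24,control,628.00,205.74,24
PANSS_P,schizophrenia,8.83,3.06,24,,,,
PANSS_N,schizophrenia,8.17,2.30,24,,,,
PANSS_G,schizophrenia,20.71,3.70,24,,,,
PANSS_S,schizophrenia,3.25,0.90,24,,,,
PANSS_T,schizophrenia,41.17,8.31,24,,,,
Duration,schizophrenia,6.74,5.53,24,,,,
CPZ Equi. Doses mg/day,schizophrenia,457.29,251.68,24,,,,
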