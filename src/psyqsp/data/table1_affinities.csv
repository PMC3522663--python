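drug,receptor,ki_nM
JNJ37822681,D1,>10000
JNJ37822681,D2,220
JNJ37822681,D3,>10000
JNJ37822681,5-HT1A,>10000
JNJ37822681,5-HT1B,>10000
JNJ37822681,5-HT1C,>10000
JNJ37822681,5-HT1D,>10000
JNJ37822681,5-HT2A,1632
JNJ37822681,5-HT2C,>10000
JNJ37822681,5-HT3,6692
JNJ37822681,5-HT6,5667
JNJ37822681,alpha1,>10000
JNJ37822681,alpha2,>10000
JNJ37822681,M1,3000
JNJ37822681,M2,>10000
JNJ37822681,beta1,>10000
JNJ37822681,beta2,>10000
JNJ37822681,H1,2571
JNJ37822681,H2,>10000
JNJ37822681,Ca-channel,3348
JNJ37822681,GABA,>10000
ocaperidone,D1,251
ocaperidone,D2,1.22
ocaperidone,D3,2.50
ocaperidone,5-HT1A,17.17
ocaperidone,5-HT1B,540
ocaperidone,5-HT1C,28
ocaperidone,5-HT1D,128.65
ocaperidone,5-HT2A,0.58
ocaperidone,5-HT2C,27.00
ocaperidone,5-HT3,750
ocaperidone,5-HT6,>10000
ocaperidone,alpha1,0.46
ocaperidone,alpha2,5.40
ocaperidone,M1,1000
ocaperidone,M2,N/A
ocaperidone,beta1,750
ocaperidone,beta2,750
ocaperidone,H1,1.6
ocaperidone,H2,500
ocaperidone,Ca-channel,1500
ocaperidone,GABA,1500
ND8295,D1,N/A
ND8295,D2,1.3
ND8295,D3,N/A
ND8295,5-HT1A,19
ND8295,5-HT1B,N/A
ND8295,5-HT1C,N/A
ND8295,5-HT1D,19
ND8295,5-HT2A,0.59
ND8295,5-HT2C,32
ND8295,5-HT3,N/A
ND8295,5-HT6,>10000
ND8295,alpha1,0.66
ND8295,alpha2,4.1
ND8295,M1,N/A
ND8295,M2,N/A
ND8295,beta1,N/A
ND8295,beta2,N/A
ND8295,H1,N/A
ND8295,H2,N/A
ND8295,Ca-channel,N/A
ND8295,GABA,N/A
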