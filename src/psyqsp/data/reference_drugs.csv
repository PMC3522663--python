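drug,receptor,ki_nM,efficacy
olanzapine,D1,70,
olanzapine,D2,31,
olanzapine,D3,49,
olanzapine,5-HT1A,>10000,
olanzapine,5-HT2A,4,
olanzapine,5-HT2C,11,
olanzapine,5-HT3,202,
olanzapine,5-HT6,10,
olanzapine,alpha1,19,
olanzapine,alpha2,230,
olanzapine,M1,26,
olanzapine,M2,48,
olanzapine,H1,2,
risperidone,D1,430,
risperidone,D2,3.3,
risperidone,D3,13,
risperidone,5-HT1A,210,
risperidone,5-HT2A,0.16,
risperidone,5-HT2C,32,
risperidone,5-HT6,>10000,
risperidone,alpha1,2.7,
risperidone,alpha2,8,
risperidone,M1,>10000,
risperidone,H1,20,
clozapine,D1,270,
clozapine,D2,157,
clozapine,D3,310,
clozapine,5-HT1A,124,0.5
clozapine,5-HT2A,8,
clozapine,5-HT2C,17,
clozapine,5-HT3,241,
clozapine,5-HT6,11,
clozapine,alpha1,7,
clozapine,alpha2,37,
clozapine,M1,1.9,
clozapine,M2,72,
clozapine,H1,1.1,
clozapine,H2,153,
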