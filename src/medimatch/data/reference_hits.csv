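medication,n_self,metabolite,n_blood,published_p,self_only,blood_only,both,cohort_n
metformin,220,metformin,846,8.7e-92,17,643,203,2807
atorvastatin,90,o-hydroxyatorvastatin,110,3.1e-76,27,47,63,2807
valsartan,40,valsartan,171,7.0e-46,2,133,38,2807
losartan,24,losartan,27,3.7e-38,5,8,19,2807
gliclazide,47,gliclazide,468,6.2e-30,4,425,43,2807
indapamide,15,indapamide,34,9.2e-25,2,21,13,2807
warfarin,9,10-hydroxywarfarin,13,2.4e-23,0,4,9,2807
atenolol,18,atenolol,140,4.8e-22,1,123,17,2807
acetylsalicylic acid,111,salicyluric glucuronide,1292,2.5e-21,13,1194,98,2807
escitalopram,10,citalopram/escitalopram,31,5.4e-21,0,21,10,2807
esomeprazole,26,omeprazole,67,7.4e-21,10,51,16,2807
glimepiride,18,glimepiride,25,1.7e-17,8,15,10,2807
topiramate,7,topiramate,20,2.9e-16,0,13,7,2807
pantoprazole,12,pantoprazole,88,4.0e-12,3,79,9,2807
celecoxib,18,celecoxib,58,1.5e-11,9,49,9,2807
pregabalin,7,pregabalin,16,6.3e-11,2,11,5,2807
fexofenadine,12,fexofenadine,57,7.2e-10,5,50,7,2807
perindopril,12,perindopril,14,1.1e-9,7,9,5,2807
pioglitazone,5,hydroxypioglitazone,23,1.7e-8,1,19,4,2807
acetaminophen,17,2-methoxyacetaminophen glucuronide,419,2.1e-8,4,406,13,2807
montelukast,5,montelukast,26,2.9e-8,1,22,4,2807
repaglinide,2,repaglinide,3,7.6e-7,0,1,2,2807
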