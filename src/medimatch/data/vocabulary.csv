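common_name,drugbank_id,atc_codes,synonyms,components
metformin,DB00331,A10BA02,Glucophage|metformin hydrochloride,
acetaminophen,DB00316,N02BE01,paracetamol|Panadol|Tylenol|APAP,
acetylsalicylic acid,DB00945,B01AC06|N02BA01|A01AD05,Aspirin|ASA|acetosal,
atorvastatin,DB01076,C10AA05,Lipitor|atorvastatin calcium,
rosuvastatin,DB01098,C10AA07,Crestor|rosuvastatin calcium,
simvastatin,DB00641,C10AA01,Zocor,
valsartan,DB00177,C09CA03,Diovan,
amlodipine,DB00381,C08CA01,Norvasc|amlodipine besylate,
Exforge,,,amlodipine and valsartan,amlodipine|valsartan
losartan,DB00678,C09CA01,Cozaar|losartan potassium,
gliclazide,DB01120,A10BB09,Diamicron,
indapamide,DB00808,C03BA11,Natrilix,
warfarin,DB00682,B01AA03,Coumadin|warfarin sodium,
atenolol,DB00335,C07AB03,Tenormin,
escitalopram,DB01175,N06AB10,Lexapro|Cipralex|escitalopram oxalate,
citalopram,DB00215,N06AB04,Celexa,
fluoxetine,DB00472,N06AB03,Prozac,
duloxetine,DB00476,N06AX21,Cymbalta,
esomeprazole,DB00736,A02BC05,Nexium|esomeprazole magnesium,
omeprazole,DB00338,A02BC01,Prilosec|Losec,
pantoprazole,DB00213,A02BC02,Protonix|Pantoloc,
glimepiride,DB00222,A10BB12,Amaryl,
topiramate,DB00273,N03AX11,Topamax,
celecoxib,DB00482,M01AH01,Celebrex,
pregabalin,DB00230,N03AX16,Lyrica,
fexofenadine,DB00950,R06AX26,Allegra|Telfast|fexofenadine hydrochloride,
perindopril,DB00790,C09AA04,Coversyl|perindopril erbumine,
pioglitazone,DB01132,A10BG03,Actos|pioglitazone hydrochloride,
montelukast,DB00471,R03DC03,Singulair|montelukast sodium,
repaglinide,DB00912,A10BX02,Prandin|NovoNorm,
levothyroxine,DB00451,H03AA01,Synthroid|Eltroxin|L-thyroxine,
insulin human,DB00030,A10AB01,Humulin|regular insulin,
ibuprofen,DB01050,M01AE01|C01EB16|G02CC01,Advil|Brufen|Nurofen,
cholecalciferol,DB00169,A11CC05,vitamin D3|vitamin D,
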