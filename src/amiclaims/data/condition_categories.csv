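code,category,description
78650,cardiac,Unspecified chest pain
4019,cardiac,Unspecified essential hypertension
41401,cardiac,Coronary atherosclerosis of native coronary vessel
41071,cardiac,"AMI, subendocardial infarction, initial episode of care"
41090,cardiac,"AMI, unspecified site, episode of care unspecified"
2724,cardiac,Other and unspecified hyperlipidemia
41070,cardiac,"AMI, subendocardial infarction, episode of care unspecified"
41400,cardiac,"Coronary atherosclerosis of unspecified vessel, native or graft"
79431,cardiac,Nonspecific abnormal electrocardiogram
4280,cardiac,"Congestive heart failure, unspecified"
4139,cardiac,Other and unspecified angina pectoris
412,cardiac,Old myocardial infarction
25000,endocrine,Type 2 diabetes mellitus without complication
496,pulmonary,"Chronic airway obstruction, not elsewhere classified"
5859,renal,"Chronic kidney disease, unspecified"
2859,hematologic,"Anemia, unspecified"
30000,neuropsychiatric,"Anxiety state, unspecified"
71590,musculoskeletal,"Osteoarthrosis, unspecified"
0389,infectious_disease,"Unspecified septicemia"
V4581,health_status,Aortocoronary bypass status
486,respiratory,"Pneumonia, organism unspecified"
4439,vascular,"Peripheral vascular disease, unspecified"
2768,metabolic,Hypopotassemia
I214,cardiac,Non-ST elevation (NSTEMI) myocardial infarction
I10,cardiac,Essential (primary) hypertension
I2510,cardiac,Atherosclerotic heart disease of native coronary artery without angina
R079,cardiac,"Chest pain, unspecified"
E785,cardiac,"Hyperlipidemia, unspecified"
I213,cardiac,ST elevation (STEMI) myocardial infarction of unspecified site
R9431,cardiac,Abnormal electrocardiogram
R0789,cardiac,Other chest pain
I509,cardiac,"Heart failure, unspecified"
I517,cardiac,Cardiomegaly
I209,cardiac,"Angina pectoris, unspecified"
I252,cardiac,Old myocardial infarction
E119,endocrine,Type 2 diabetes mellitus without complications
J449,pulmonary,"Chronic obstructive pulmonary disease, unspecified"
N179,renal,"Acute kidney failure, unspecified"
D649,hematologic,"Anemia, unspecified"
F419,neuropsychiatric,"Anxiety disorder, unspecified"
M545,musculoskeletal,Low back pain
A419,infectious_disease,"Sepsis, unspecified organism"
Z951,health_status,Presence of aortocoronary bypass graft
J189,respiratory,"Pneumonia, unspecified organism"
I739,vascular,"Peripheral vascular disease, unspecified"
E875,metabolic,Hyperkalemia
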