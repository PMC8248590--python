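product_code,product_name,category,drug_class
D0001,metoprolol tartrate,cardiac,beta_blocker
D0002,carvedilol,cardiac,beta_blocker
D0003,atenolol,cardiac,beta_blocker
D0004,metoprolol succinate,cardiac,beta_blocker
D0005,atorvastatin calcium,cardiac,anti_lipid
D0006,simvastatin,cardiac,anti_lipid
D0007,rosuvastatin calcium,cardiac,anti_lipid
D0008,clopidogrel bisulfate,cardiac,anti_platelet
D0009,ticagrelor,cardiac,anti_platelet
D0010,prasugrel,cardiac,anti_platelet
D0011,lisinopril,cardiac,ace_arb
D0012,losartan potassium,cardiac,ace_arb
D0013,hydrochlorothiazide/lisinopril,cardiac,ace_arb
D0014,nitroglycerin,cardiac,anti_anginal
D0015,isosorbide mononitrate,cardiac,anti_anginal
D0016,furosemide,cardiac,diuretic
D0017,hydrochlorothiazide,cardiac,diuretic
D0018,amlodipine besylate,cardiac,calcium_channel_blocker
D0019,diltiazem,cardiac,calcium_channel_blocker
D0020,digoxin,cardiac,other
D0021,warfarin sodium,cardiac,other
D9001,levothyroxine,endocrine,
D9002,omeprazole,gastrointestinal,
D9003,metformin,endocrine,
D9004,amoxicillin,infectious_disease,
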