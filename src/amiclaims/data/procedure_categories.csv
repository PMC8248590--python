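code,category,description
99232,evaluation_management,"Subsequent hospital care, expanded problem focused"
99223,evaluation_management,"Initial hospital care, high complexity"
99285,evaluation_management,"Emergency department visit, comprehensive"
99233,evaluation_management,"Subsequent hospital care, high complexity"
99291,evaluation_management,"Critical care, first 30-74 minutes"
99214,evaluation_management,"Office visit, established patient, moderate complexity"
99239,evaluation_management,"Hospital discharge day management, more than 30 minutes"
99222,evaluation_management,"Initial hospital care, moderate complexity"
99238,evaluation_management,"Hospital discharge day management, 30 minutes or less"
99213,evaluation_management,"Office visit, established patient, expanded problem focused"
99231,evaluation_management,"Subsequent hospital care, problem focused"
93000,procedure,"Routine EKG with tracing, interpretation and report"
93005,procedure,"Routine EKG, tracing only"
93010,procedure,"Routine EKG, interpretation and report only"
A0427,emergency_medical_services,"Ambulance service, ALS emergency transport"
71045,imaging,"Radiologic examination, chest, single view"
71046,imaging,"Radiologic examination, chest, 2 views"
80053,laboratory,Comprehensive metabolic panel
80061,laboratory,Lipid panel
85025,laboratory,Complete blood count with differential
36415,laboratory,Collection of venous blood by venipuncture
88305,pathology,"Surgical pathology, level IV"
93306,ultrasound_doppler,Transthoracic echocardiography with doppler
96372,medication_management,Therapeutic injection
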