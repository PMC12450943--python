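pt,soc_name,soc_code
Drug ineffective,General disorders and administration site conditions,10018065
Pain,General disorders and administration site conditions,10018065
Condition aggravated,General disorders and administration site conditions,10018065
Injection site erythema,General disorders and administration site conditions,10018065
Injection site pruritus,General disorders and administration site conditions,10018065
Injection site swelling,General disorders and administration site conditions,10018065
Injection site reaction,General disorders and administration site conditions,10018065
Injection site rash,General disorders and administration site conditions,10018065
Injection site bruising,General disorders and administration site conditions,10018065
Injection site urticaria,General disorders and administration site conditions,10018065
Injection site mass,General disorders and administration site conditions,10018065
Injection site warmth,General disorders and administration site conditions,10018065
Injection site irritation,General disorders and administration site conditions,10018065
Gait disturbance,General disorders and administration site conditions,10018065
Gait inability,General disorders and administration site conditions,10018065
Peripheral swelling,General disorders and administration site conditions,10018065
Swelling,General disorders and administration site conditions,10018065
Illness,General disorders and administration site conditions,10018065
Inflammation,General disorders and administration site conditions,10018065
Therapeutic response decreased,General disorders and administration site conditions,10018065
Therapeutic response shortened,General disorders and administration site conditions,10018065
Fatigue,General disorders and administration site conditions,10018065
Malaise,General disorders and administration site conditions,10018065
Pyrexia,General disorders and administration site conditions,10018065
Arthralgia,Musculoskeletal and connective tissue disorders,10028395
Rheumatoid arthritis,Musculoskeletal and connective tissue disorders,10028395
Joint swelling,Musculoskeletal and connective tissue disorders,10028395
Musculoskeletal stiffness,Musculoskeletal and connective tissue disorders,10028395
Mobility decreased,Musculoskeletal and connective tissue disorders,10028395
Joint stiffness,Musculoskeletal and connective tissue disorders,10028395
Systemic lupus erythematosus,Musculoskeletal and connective tissue disorders,10028395
Polymyalgia rheumatica,Musculoskeletal and connective tissue disorders,10028395
Hand deformity,Musculoskeletal and connective tissue disorders,10028395
Product use in unapproved indication,"Injury, poisoning and procedural complications",10022117
Product dose omission in error,"Injury, poisoning and procedural complications",10022117
Intentional dose omission,"Injury, poisoning and procedural complications",10022117
Fall,"Injury, poisoning and procedural complications",10022117
COVID-19,Infections and infestations,10021881
Infection,Infections and infestations,10021881
Nasopharyngitis,Infections and infestations,10021881
Sinusitis,Infections and infestations,10021881
Diverticulitis,Infections and infestations,10021881
Ear infection,Infections and infestations,10021881
Localised infection,Infections and infestations,10021881
Pneumonia,Infections and infestations,10021881
Urinary tract infection,Infections and infestations,10021881
Rash,Skin and subcutaneous tissue disorders,10040785
Pruritus,Skin and subcutaneous tissue disorders,10040785
Alopecia,Skin and subcutaneous tissue disorders,10040785
Urticaria,Skin and subcutaneous tissue disorders,10040785
Nausea,Gastrointestinal disorders,10017947
Diarrhoea,Gastrointestinal disorders,10017947
Stomatitis,Gastrointestinal disorders,10017947
Abdominal discomfort,Gastrointestinal disorders,10017947
Gastrointestinal perforation,Gastrointestinal disorders,10017947
White blood cell count decreased,Investigations,10022891
Hepatic enzyme increased,Investigations,10022891
Blood cholesterol increased,Investigations,10022891
Neutrophil count decreased,Investigations,10022891
Oropharyngeal pain,"Respiratory, thoracic and mediastinal disorders",10038738
Rhinorrhoea,"Respiratory, thoracic and mediastinal disorders",10038738
Nasal congestion,"Respiratory, thoracic and mediastinal disorders",10038738
Cough,"Respiratory, thoracic and mediastinal disorders",10038738
Headache,Nervous system disorders,10029205
Dizziness,Nervous system disorders,10029205
Paraesthesia,Nervous system disorders,10029205
Loss of consciousness,Nervous system disorders,10029205
Seizure,Nervous system disorders,10029205
Memory impairment,Nervous system disorders,10029205
Loss of personal independence in daily activities,Social circumstances,10041244
Surgery,Surgical and medical procedures,10042613
Knee arthroplasty,Surgical and medical procedures,10042613
Insomnia,Psychiatric disorders,10037175
Anxiety,Psychiatric disorders,10037175
Depression,Psychiatric disorders,10037175
Anaphylactic reaction,Immune system disorders,10021428
Hypersensitivity,Immune system disorders,10021428
Hypertension,Vascular disorders,10047065
Hypotension,Vascular disorders,10047065
Anaemia,Blood and lymphatic system disorders,10005329
Neutropenia,Blood and lymphatic system disorders,10005329
Palpitations,Cardiac disorders,10007541
Tachycardia,Cardiac disorders,10007541
Bradycardia,Cardiac disorders,10007541
Electrocardiogram QT prolonged,Cardiac disorders,10007541
Drug-induced liver injury,Hepatobiliary disorders,10019805
Hepatotoxicity,Hepatobiliary disorders,10019805
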