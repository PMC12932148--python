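PT	SOC
Diarrhoea	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Abdominal pain upper	Gastrointestinal disorders
Abdominal discomfort	Gastrointestinal disorders
Abdominal distension	Gastrointestinal disorders
Retching	Gastrointestinal disorders
Dyspepsia	Gastrointestinal disorders
Dysphagia	Gastrointestinal disorders
Flatulence	Gastrointestinal disorders
Gastrointestinal disorder	Gastrointestinal disorders
Gastrooesophageal reflux disease	Gastrointestinal disorders
Irritable bowel syndrome	Gastrointestinal disorders
Rectal haemorrhage	Gastrointestinal disorders
Intestinal obstruction	Gastrointestinal disorders
Abnormal faeces	Gastrointestinal disorders
Oral discomfort	Gastrointestinal disorders
Tooth discolouration	Gastrointestinal disorders
Tooth fracture	Gastrointestinal disorders
Steatorrhoea	Gastrointestinal disorders
Product solubility abnormal	Product issues
Product taste abnormal	Product issues
Product substitution issue	Product issues
Product physical consistency issue	Product issues
Product use complaint	Product issues
Product odour abnormal	Product issues
Product residue present	Product issues
Product quality issue	Product issues
Product physical issue	Product issues
Product packaging difficult to open	Product issues
Product availability issue	Product issues
Poor quality product administered	Product issues
Off label use	Injury, poisoning and procedural complications
Product use in unapproved indication	Injury, poisoning and procedural complications
Product use issue	Injury, poisoning and procedural complications
Intentional product use issue	Injury, poisoning and procedural complications
Foreign body in throat	Injury, poisoning and procedural complications
Foreign body in mouth	Injury, poisoning and procedural complications
Foreign body in respiratory tract	Injury, poisoning and procedural complications
Drug ineffective	General disorders and administration site conditions
Drug ineffective for unapproved indication	General disorders and administration site conditions
Drug effective for unapproved indication	General disorders and administration site conditions
Therapeutic response unexpected	General disorders and administration site conditions
Illness	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Cough	Respiratory, thoracic and mediastinal disorders
Oropharyngeal pain	Respiratory, thoracic and mediastinal disorders
Oropharyngeal discomfort	Respiratory, thoracic and mediastinal disorders
Dysphonia	Respiratory, thoracic and mediastinal disorders
Choking	Respiratory, thoracic and mediastinal disorders
Choking sensation	Respiratory, thoracic and mediastinal disorders
Throat irritation	Respiratory, thoracic and mediastinal disorders
Throat tightness	Respiratory, thoracic and mediastinal disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Blood glucose increased	Investigations
Weight decreased	Investigations
Prothrombin time prolonged	Investigations
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Dysgeusia	Nervous system disorders
Somnolence	Nervous system disorders
Syncope	Nervous system disorders
Paraesthesia	Nervous system disorders
Rash	Skin and subcutaneous tissue disorders
Urticaria	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Osteoporosis	Musculoskeletal and connective tissue disorders
Decreased appetite	Metabolism and nutrition disorders
Vitamin D deficiency	Metabolism and nutrition disorders
Anxiety	Psychiatric disorders
Insomnia	Psychiatric disorders
Hypersensitivity	Immune system disorders
Reaction to excipient	Immune system disorders
Nasopharyngitis	Infections and infestations
Haematuria	Renal and urinary disorders
Biliary colic	Hepatobiliary disorders
Vision blurred	Eye disorders
Night blindness	Eye disorders
Palpitations	Cardiac disorders
Hypertension	Vascular disorders
Anaemia	Blood and lymphatic system disorders
Tinnitus	Ear and labyrinth disorders
Hypothyroidism	Endocrine disorders
Uveitis	Eye disorders
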