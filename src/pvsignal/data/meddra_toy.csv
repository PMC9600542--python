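pt,primary_soc,hlt,hlgt
Ear pain,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Ear discomfort,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Otorrhoea,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Ear pruritus,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Ear congestion,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Ear swelling,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Ear disorder,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Tympanic membrane perforation,Ear and labyrinth disorders,Tympanic membrane disorders (excl infections),Middle ear disorders (excl congenital)
Deafness unilateral,Ear and labyrinth disorders,Hearing losses,Hearing disorders
Vertigo positional,Ear and labyrinth disorders,Vertigos NEC,Inner ear and VIIIth cranial nerve disorders
Middle ear effusion,Ear and labyrinth disorders,Middle ear disorders NEC,Middle ear disorders (excl congenital)
Meniere's disease,Ear and labyrinth disorders,Meniere's disease,Inner ear and VIIIth cranial nerve disorders
Cerumen impaction,Ear and labyrinth disorders,External ear disorders NEC,External ear disorders (excl congenital)
Tympanic membrane disorder,Ear and labyrinth disorders,Tympanic membrane disorders (excl infections),Middle ear disorders (excl congenital)
Tympanic membrane scarring,Ear and labyrinth disorders,Tympanic membrane disorders (excl infections),Middle ear disorders (excl congenital)
Eustachian tube obstruction,Ear and labyrinth disorders,Eustachian tube disorders,Middle ear disorders (excl congenital)
Eustachian tube disorder,Ear and labyrinth disorders,Eustachian tube disorders,Middle ear disorders (excl congenital)
Eosinophilic granulomatosis with polyangiitis,Vascular disorders,Vasculitides,Vascular inflammations
Eosinophilia,Blood and lymphatic system disorders,Eosinophilic disorders,White blood cell disorders
Eosinophil count increase,Investigations,White blood cell analyses,Haematology investigations (incl blood groups)
Eosinophilic pneumonia,"Respiratory, thoracic and mediastinal disorders",Eosinophilic pneumonias,Lower respiratory tract disorders (excl obstruction and infection)
Eosinophilic oesophagitis,Gastrointestinal disorders,Oesophagitis and oesophageal ulceration,Oesophageal disorders
Hypereosinophilic syndrome,Blood and lymphatic system disorders,Eosinophilic disorders,White blood cell disorders
Eosinophilic pneumonia chronic,"Respiratory, thoracic and mediastinal disorders",Eosinophilic pneumonias,Lower respiratory tract disorders (excl obstruction and infection)
Eosinophil count abnormal,Investigations,White blood cell analyses,Haematology investigations (incl blood groups)
Eosinophilic bronchitis,"Respiratory, thoracic and mediastinal disorders",Bronchial conditions NEC,Bronchial disorders (excl neoplasms)
Asthma,"Respiratory, thoracic and mediastinal disorders",Bronchospasm and obstruction,Bronchial disorders (excl neoplasms)
Cough,"Respiratory, thoracic and mediastinal disorders",Coughing and associated symptoms,Respiratory disorders NEC
Dyspnoea,"Respiratory, thoracic and mediastinal disorders",Breathing abnormalities,Respiratory disorders NEC
Wheezing,"Respiratory, thoracic and mediastinal disorders",Breathing abnormalities,Respiratory disorders NEC
Fatigue,General disorders and administration site conditions,Asthenic conditions,General system disorders NEC
Pyrexia,General disorders and administration site conditions,Febrile disorders,Body temperature conditions
Injection site reaction,General disorders and administration site conditions,Injection site reactions,Administration site reactions
Chest pain,General disorders and administration site conditions,Pain and discomfort NEC,General system disorders NEC
Headache,Nervous system disorders,Headaches NEC,Headaches
Dizziness,Nervous system disorders,Neurological signs and symptoms NEC,Neurological disorders NEC
Migraine,Nervous system disorders,Migraine headaches,Headaches
Rash,Skin and subcutaneous tissue disorders,Rashes eruptions and exanthems NEC,Epidermal and dermal conditions
Urticaria,Skin and subcutaneous tissue disorders,Urticarias,Angioedema and urticaria
Pruritus,Skin and subcutaneous tissue disorders,Pruritus NEC,Epidermal and dermal conditions
Alopecia,Skin and subcutaneous tissue disorders,Alopecias,Skin appendage conditions
Nausea,Gastrointestinal disorders,Nausea and vomiting symptoms,Gastrointestinal signs and symptoms
Vomiting,Gastrointestinal disorders,Nausea and vomiting symptoms,Gastrointestinal signs and symptoms
Diarrhoea,Gastrointestinal disorders,Diarrhoea (excl infective),Gastrointestinal motility and defaecation conditions
Abdominal pain,Gastrointestinal disorders,Gastrointestinal and abdominal pains,Gastrointestinal signs and symptoms
Arthralgia,Musculoskeletal and connective tissue disorders,Joint related signs and symptoms,Joint disorders
Myalgia,Musculoskeletal and connective tissue disorders,Muscle pains,Muscle disorders
Back pain,Musculoskeletal and connective tissue disorders,Musculoskeletal and connective tissue pain and discomfort,Musculoskeletal and connective tissue disorders NEC
Anaphylactic reaction,Immune system disorders,Anaphylactic responses,Allergic conditions
Hypersensitivity,Immune system disorders,Allergic conditions NEC,Allergic conditions
Nasopharyngitis,Infections and infestations,Upper respiratory tract infections,Infections - pathogen unspecified
Sinusitis,Infections and infestations,Upper respiratory tract infections,Infections - pathogen unspecified
Otitis media,Infections and infestations,Ear infections,Infections - pathogen unspecified
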