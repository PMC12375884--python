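pt	hlt	hlgt	soc	primary
Influenza	Influenza viral infections	Viral infectious disorders	Infections and infestations	Y
Herpes zoster	Herpes viral infections	Viral infectious disorders	Infections and infestations	Y
Gastroenteritis viral	Viral gastrointestinal infections	Viral infectious disorders	Infections and infestations	Y
Viral infection	Viral infections NEC	Viral infectious disorders	Infections and infestations	Y
Pneumonia	Lower respiratory tract infections	Infections - pathogen unspecified	Infections and infestations	Y
Urinary tract infection	Urinary tract infections	Infections - pathogen unspecified	Infections and infestations	Y
Sepsis	Sepsis, bacteraemia, viraemia and fungaemia NEC	Infections - pathogen unspecified	Infections and infestations	Y
Meningococcal sepsis	Neisseria infections	Bacterial infectious disorders	Infections and infestations	Y
Nasopharyngitis	Upper respiratory tract infections	Infections - pathogen unspecified	Infections and infestations	Y
Cellulitis	Skin structures and soft tissue infections	Infections - pathogen unspecified	Infections and infestations	Y
COVID-19	Coronavirus infections	Viral infectious disorders	Infections and infestations	Y
Pyrexia	Febrile disorders	Body temperature conditions	General disorders and administration site conditions	Y
Fatigue	Asthenic conditions	General system disorders NEC	General disorders and administration site conditions	Y
Asthenia	Asthenic conditions	General system disorders NEC	General disorders and administration site conditions	Y
Chills	Feelings and sensations NEC	General system disorders NEC	General disorders and administration site conditions	Y
Drug ineffective	Therapeutic and nontherapeutic responses	Therapeutic and nontherapeutic effects	General disorders and administration site conditions	Y
Haemolysis	Haemolyses NEC	Red blood cell disorders	Blood and lymphatic system disorders	Y
Anaemia	Anaemias NEC	Anaemias nonhaemolytic and marrow depression	Blood and lymphatic system disorders	Y
Haemoglobin decreased	Red blood cell analyses	Haematology investigations	Investigations	Y
Headache	Headaches NEC	Headaches	Nervous system disorders	Y
Dizziness	Neurological signs and symptoms NEC	Neurological disorders NEC	Nervous system disorders	Y
Nausea	Nausea and vomiting symptoms	Gastrointestinal signs and symptoms	Gastrointestinal disorders	Y
Vomiting	Nausea and vomiting symptoms	Gastrointestinal signs and symptoms	Gastrointestinal disorders	Y
Diarrhoea	Diarrhoea (excl infective)	Gastrointestinal motility and defaecation conditions	Gastrointestinal disorders	Y
Abdominal pain	Gastrointestinal and abdominal pains (excl oral and throat)	Gastrointestinal signs and symptoms	Gastrointestinal disorders	Y
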