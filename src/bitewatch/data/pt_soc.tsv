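preferred_term	soc
Ageusia	Nervous system disorders
Agnosia	Nervous system disorders
Altered state of consciousness	Nervous system disorders
Anosmia	Nervous system disorders
Aphasia	Nervous system disorders
Apraxia	Nervous system disorders
Ataxia	Nervous system disorders
Central nervous system haemorrhage	Nervous system disorders
Central nervous system lesion	Nervous system disorders
Cerebellar syndrome	Nervous system disorders
Cerebral haemorrhage	Nervous system disorders
Dysgeusia	Nervous system disorders
Dysgraphia	Nervous system disorders
Dysmetria	Nervous system disorders
Encephalopathy	Nervous system disorders
Facial paralysis	Nervous system disorders
Facial paresis	Nervous system disorders
Febrile convulsion	Nervous system disorders
Generalised tonic-clonic seizure	Nervous system disorders
Guillain-Barre syndrome	Nervous system disorders
Haemorrhage intracranial	Nervous system disorders
Hyporesponsive to stimuli	Nervous system disorders
IIIrd nerve paralysis	Nervous system disorders
Immune effector cell-associated neurotoxicity syndrome	Nervous system disorders
Intention tremor	Nervous system disorders
Intracranial pressure increased	Nervous system disorders
Leukoencephalopathy	Nervous system disorders
Lumbosacral radiculopathy	Nervous system disorders
Movement disorder	Nervous system disorders
Nervous system disorder	Nervous system disorders
Neurological symptom	Nervous system disorders
Neuropathy peripheral	Nervous system disorders
Neurotoxicity	Nervous system disorders
Parkinsonism	Nervous system disorders
Peripheral motor neuropathy	Nervous system disorders
Peripheral sensory neuropathy	Nervous system disorders
Peroneal nerve palsy	Nervous system disorders
Postictal state	Nervous system disorders
Radiculopathy	Nervous system disorders
Resting tremor	Nervous system disorders
Seizure	Nervous system disorders
Slow response to stimuli	Nervous system disorders
Spinal cord compression	Nervous system disorders
Status epilepticus	Nervous system disorders
Subdural hygroma	Nervous system disorders
Superior sagittal sinus thrombosis	Nervous system disorders
Taste disorder	Nervous system disorders
Tonic convulsion	Nervous system disorders
Toxic leukoencephalopathy	Nervous system disorders
Transient aphasia	Nervous system disorders
Tremor	Nervous system disorders
Unresponsive to stimuli	Nervous system disorders
VIth nerve paralysis	Nervous system disorders
White matter lesion	Nervous system disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Pyrexia	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Oedema peripheral	General disorders and administration site conditions
Cytokine release syndrome	Immune system disorders
Anaemia	Blood and lymphatic system disorders
Neutropenia	Blood and lymphatic system disorders
Thrombocytopenia	Blood and lymphatic system disorders
Rash	Skin and subcutaneous tissue disorders
Pneumonia	Infections and infestations
Urinary tract infection	Infections and infestations
Hypotension	Vascular disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
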