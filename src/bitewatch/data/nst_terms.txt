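Ageusia
Agnosia
Altered state of consciousness
Anosmia
Aphasia
Apraxia
Ataxia
Central nervous system haemorrhage
Central nervous system lesion
Cerebellar syndrome
Cerebral haemorrhage
Dysgeusia
Dysgraphia
Dysmetria
Encephalopathy
Facial paralysis
Facial paresis
Febrile convulsion
Generalised tonic-clonic seizure
Guillain-Barre syndrome
Haemorrhage intracranial
Hyporesponsive to stimuli
IIIrd nerve paralysis
Immune effector cell-associated neurotoxicity syndrome
Intention tremor
Intracranial pressure increased
Leukoencephalopathy
Lumbosacral radiculopathy
Movement disorder
Nervous system disorder
Neurological symptom
Neuropathy peripheral
Neurotoxicity
Parkinsonism
Peripheral motor neuropathy
Peripheral sensory neuropathy
Peroneal nerve palsy
Postictal state
Radiculopathy
Resting tremor
Seizure
Slow response to stimuli
Spinal cord compression
Status epilepticus
Subdural hygroma
Superior sagittal sinus thrombosis
Taste disorder
Tonic convulsion
Toxic leukoencephalopathy
Transient aphasia
Tremor
Unresponsive to stimuli
VIth nerve paralysis
White matter lesion
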