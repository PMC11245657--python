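# synthrisk coefficient table v1
# sex: female
# training_period: 2002-2010
# control_sampling_fraction: 0.01
predictor,coefficient,odds_ratio,p_value
Age,0.00,1.00,<.001
Rural town _48m,0.19,1.21,<.001
Material deprivation_2,-0.06,0.94,.38
Hospitalisation for Suicide attempt_60m,1.85,6.36,<.001
Hospitalisation for Physical health reasons_24m,0.35,1.42,<.001
Hospitalisation for mental health reasons_36m,0.37,1.45,<.001
Duration of hospitalisation for Physical health reasons_6m,0.007,1.01,.01
Emergency room visits for mental health reasons_60m,1.13,3.10,<.001
Outpatient psychiatrist visits for mental health reasons_60m,0.66,1.93,<.001
Outpatient GP visits for mental health reasons_36m,-0.01,0.99,.94
Mood and anxiety disorders_12m,1.05,2.86,<.001
Bipolar disorders_60m,0.08,1.08,.31
Substance use disorders_60m,0.84,2.32,<.001
Endocrine system disorder_60m,-0.25,0.78,<.001
Personality disorders_60m,0.47,1.60,<.001
Dementia_60m,-0.65,0.52,<.001
Genito-urinary disorders_48m,-0.23,0.79,<.001
"Symptoms, Signs and Ill-defined Conditions_12m",0.22,1.25,<.001
Non-intentional trauma _36m,0.41,1.51,<.001
Respiratory disorders_24m,-0.10,0.90,.04
Other mental disorders_60m,0.10,1.11,.02
Infectious disease_36m,0.13,1.14,.01
Constant,-6.47,,
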