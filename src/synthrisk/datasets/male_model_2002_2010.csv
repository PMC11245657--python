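# synthrisk coefficient table v1
# sex: male
# training_period: 2002-2010
# control_sampling_fraction: 0.01
predictor,coefficient,odds_ratio,p_value
Age,0.01,1.01,<.001
Charlson score,0.11,1.12,.01
Rural town _60m,0.44,1.55,<.001
Hospitalisation for Suicide attempt_60m,1.88,6.55,<.001
Emergency room visits for Physical health reasons_3m,1.00,2.72,<.001
Outpatient psychiatrist visits for mental health reasons_60m,0.67,1.95,<.001
Outpatient GP visits for Physical health reasons_60m,-0.15,0.86,<.001
Psychotherapy visits with a GP_3m,0.24,1.27,<.001
Mood and anxiety disorders_60m,0.99,2.69,<.001
Substance use disorders_60m,0.89,2.44,<.001
Personality disorders_60m,0.41,1.51,<.001
Respiratory disorders_60m,-0.28,0.76,<.001
Other mental disorders_60m,0.26,1.30,<.001
"Symptoms, Signs and Ill-defined Conditions_3m",0.13,1.14,<.001
Non-intentional trauma _48m,0.21,1.23,<.001
Infectious disease_6m,0.30,1.35,<.001
Endocrine system disorder_48m,-0.15,0.86,<.001
Genito-urinary disorders_24m,-0.08,0.92,.01
Cancer_60m,-0.15,0.86,<.001
Regional mental budget,-0.001,1.00,<.001
Constant,-4.85,,
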