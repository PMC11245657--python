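variable,level,male_control_n,male_control_pct,male_case_n,male_case_pct,female_control_n,female_control_pct,female_case_n,female_case_pct
Age (years),15-39,122712,38.76,1948,29.01,120116,36.50,612,27.99
Age (years),40-59,108687,34.33,2998,44.65,108740,33.05,1043,47.71
Age (years),>=60,85175,26.90,1767,26.32,100160,30.44,531,24.29
Urbanicity,Rural town,62682,19.80,1962,29.22,60449,18.37,478,21.86
Social deprivation score,1 (most privileged),60096,18.98,1167,17.38,59127,17.97,310,14.18
Social deprivation score,2,60283,19.04,1323,19.70,60002,18.23,339,15.50
Social deprivation score,3,59937,18.93,1223,18.21,61491,18.68,358,16.37
Social deprivation score,4,58681,18.53,1162,17.30,62807,19.08,427,19.53
Social deprivation score,5 (most deprived),58620,18.51,1427,21.25,63683,19.35,592,27.08
Material deprivation score,1 (most privileged),58609,18.51,875,13.03,62815,19.09,323,14.77
Material deprivation score,2,58650,18.52,1034,15.40,61194,18.59,365,16.69
Material deprivation score,3,60167,19.00,1274,18.97,61428,18.67,378,17.29
Material deprivation score,4,60102,18.98,1450,21.59,61349,18.64,449,20.53
Material deprivation score,5 (most deprived),60089,18.98,1669,24.86,60324,18.33,511,23.37
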