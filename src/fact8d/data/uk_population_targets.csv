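variable,category,population_share,sample_share
sex,male,0.487,0.486
sex,female,0.513,0.514
age_group,18-29,0.201,0.200
age_group,30-39,0.165,0.164
age_group,40-49,0.174,0.175
age_group,50-59,0.166,0.167
age_group,60-69,0.139,0.138
age_group,70+,0.156,0.156
country_of_birth,england,0.719,0.786
country_of_birth,other_uk,0.155,0.131
country_of_birth,ireland_or_other_english,0.015,0.027
country_of_birth,non_english_speaking,0.111,0.055
education,level1_or_lower,0.373,0.127
education,level2,0.185,0.153
education,level3,0.121,0.159
education,level4,0.270,0.505
education,other,0.051,0.056
marital_status,single,0.347,0.354
marital_status,married_or_civil_partnership,0.467,0.493
marital_status,other,0.185,0.153
household_ownership,owns,0.650,0.710
household_ownership,rents,0.320,0.270
household_ownership,rent_free,0.030,0.020
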