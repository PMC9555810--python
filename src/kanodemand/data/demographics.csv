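covariate,level,count
gender,Female,196
gender,Male,152
age_band,65-74,221
age_band,75-84,113
age_band,85 and above,14
education,Illiterate or barely literate,78
education,Primary school,97
education,Junior high school,92
education,Senior high school or technical secondary school,44
education,Junior college diploma or higher,37
residence_city,Urban (Yangzhou),87
residence_city,Urban (Nantong),88
residence_city,Rural (Yangzhou),86
residence_city,Rural (Nantong),87
living_condition,Living alone,155
living_condition,With spouse,193
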