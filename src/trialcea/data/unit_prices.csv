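item,unit,price_eur,price_year
gp_visits,visit,33.00,2016
gp_support,visit,17.00,2016
social_worker,visit,66.00,2016
psychologist,visit,94.00,2016
physiotherapist,visit,33.00,2016
psychiatry,visit,106.00,2016
other_visits,visit,60.00,2016
drug_days_depression,day,2.00,2016
drug_days_sleep,day,1.00,2016
drug_days_anxiety,day,1.50,2016
home_care_hours,hour,27.00,2016
special_home_care_hours,hour,40.00,2016
informal_care_hours,hour,14.00,2016
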