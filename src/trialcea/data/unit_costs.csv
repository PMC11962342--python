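resource,unit,unit_cost_eur,source_year
rtms_session,session,248.00,2022
psychotherapy_session,session,100.00,2022
gp_contact,contact,33.00,2022
mental_care_contact,contact,120.00,2022
other_care_contact,contact,40.00,2022
home_help_hour,hour,18.00,2022
medication_day,day,0.40,2022
travel_trip,trip,5.00,2022
housekeeping_hour,hour,18.00,2022
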