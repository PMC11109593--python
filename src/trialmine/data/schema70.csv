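entity_id,name,kind,parent_id,value_unit,arm_scoped
mean_age,Mean age of participants,value,,years,false
min_age,Minimum age of participants,value,,years,false
pct_female,Proportion identifying as female,value,,percent,false
mean_cigs_per_day,Mean number of times tobacco used,value,,cigarettes per day,false
n_randomised,Number of participants randomised,value,,participants,true
n_analysed,Number of participants analysed,value,,participants,true
mean_years_smoking,Mean duration of smoking,value,,years,false
dependence_score,Nicotine dependence score,value,,points,false
baseline_co_ppm,Baseline expired carbon monoxide,value,,ppm,false
motivation_score,Motivation to quit score,value,,points,false
followup_longest_weeks,Longest follow-up,value,,weeks,false
dose_mg,Medication dose,value,,mg,true
sessions_count,Number of contact sessions,value,,sessions,true
session_minutes,Session duration,value,,minutes,true
intervention_weeks,Intervention duration,value,,weeks,true
attrition_pct,Attrition proportion,value,,percent,true
mean_quit_attempts,Mean previous quit attempts,value,,attempts,false
outcome_abstinence_6m,Percent abstinent at 6 months,value,,percent,true
outcome_abstinence_12m,Percent abstinent at 12 months,value,,percent,true
bct_goal_setting,Goal setting (behaviour),presence_absence,,,true
bct_problem_solving,Problem solving,presence_absence,,,true
bct_action_planning,Action planning,presence_absence,,,true
bct_self_monitoring,Self-monitoring of behaviour,presence_absence,,,true
bct_feedback,Feedback on behaviour,presence_absence,,,true
bct_social_support,Social support (unspecified),presence_absence,,,true
bct_health_consequences,Information about health consequences,presence_absence,,,true
bct_reward,Reward (outcome),presence_absence,,,true
bct_pros_cons,Pros and cons,presence_absence,,,true
bct_reduce_negative_emotions,Reduce negative emotions,presence_absence,,,true
drug_nrt,Nicotine replacement therapy,presence_absence,,,true
drug_varenicline,Varenicline,presence_absence,,,true
drug_bupropion,Bupropion,presence_absence,,,true
drug_cytisine,Cytisine,presence_absence,,,true
drug_ecig,E-cigarettes,presence_absence,,,true
delivery_face_to_face,Face-to-face delivery,presence_absence,,,true
delivery_phone,Telephone delivery,presence_absence,,,true
delivery_text,Text-message delivery,presence_absence,,,true
delivery_app,App-based delivery,presence_absence,,,true
delivery_website,Website delivery,presence_absence,,,true
delivery_printed,Printed material,presence_absence,,,true
delivery_group,Group-based format,presence_absence,,,true
delivery_individual,Individual format,presence_absence,,,true
provider_doctor,Delivered by physician,presence_absence,,,true
provider_nurse,Delivered by nurse,presence_absence,,,true
provider_counsellor,Delivered by counsellor,presence_absence,,,true
provider_pharmacist,Delivered by pharmacist,presence_absence,,,true
setting_primary_care,Primary-care setting,presence_absence,,,false
setting_hospital,Hospital setting,presence_absence,,,false
setting_workplace,Workplace setting,presence_absence,,,false
setting_community,Community setting,presence_absence,,,false
control_usual_care,Usual-care comparator,presence_absence,,,true
incentive_financial,Financial incentives,presence_absence,,,true
verification_biochemical,Biochemical verification of abstinence,presence_absence,,,false
population_pregnant,Pregnant population,presence_absence,,,false
population_mental_health,Mental-health population,presence_absence,,,false
population_low_ses,Low socioeconomic-status population,presence_absence,,,false
recruitment_proactive,Proactive recruitment,presence_absence,,,false
abstinence_continuous,Continuous abstinence measure,presence_absence,,,false
abstinence_point_prevalence,Point-prevalence abstinence measure,presence_absence,,,false
ethnicity_reported,Ethnicity distribution reported,presence_absence,,,false
employment_reported,Employment status reported,presence_absence,,,false
education_reported,Educational attainment reported,presence_absence,,,false
ethnicity_white_pct,Percent White,complex_component,ethnicity_reported,percent,false
ethnicity_black_pct,Percent Black,complex_component,ethnicity_reported,percent,false
ethnicity_asian_pct,Percent Asian,complex_component,ethnicity_reported,percent,false
ethnicity_other_pct,Percent other ethnicity,complex_component,ethnicity_reported,percent,false
employment_employed_pct,Percent employed,complex_component,employment_reported,percent,false
employment_unemployed_pct,Percent unemployed,complex_component,employment_reported,percent,false
education_higher_pct,Percent with higher education,complex_component,education_reported,percent,false
education_secondary_pct,Percent with secondary education,complex_component,education_reported,percent,false
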