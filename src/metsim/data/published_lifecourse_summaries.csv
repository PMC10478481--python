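sex,education,scenario,life_course_prevalence_pct,lcp_lo,lcp_hi,mean_age_onset,onset_lo,onset_hi,mean_duration,dur_lo,dur_hi
female,high,observed,32.5,30.7,33.9,45.4,44.7,46.2,6.7,6.4,7.0
female,low,observed,59.3,57.8,60.6,43.5,42.9,44.1,9.0,8.7,9.3
female,low,counterfactual_smoking,57.2,55.6,58.5,43.7,43.1,44.3,8.8,8.6,9.1
female,low,counterfactual_alcohol,58.0,56.6,59.4,43.6,43.0,44.2,8.8,8.6,9.1
female,low,counterfactual_health_literacy,58.5,57.0,59.8,43.6,43.0,44.2,8.9,8.7,9.2
female,low,counterfactual_diet,58.7,57.2,60.0,43.5,43.0,44.1,8.9,8.7,9.2
female,low,counterfactual_joint,54.5,53.0,55.9,43.9,43.3,44.5,8.6,8.3,8.8
male,high,observed,43.2,40.9,44.5,44.8,44.0,45.5,7.0,6.7,7.2
male,low,observed,71.5,70.2,72.9,42.1,41.6,42.8,9.9,9.6,10.2
male,low,counterfactual_smoking,69.4,68.1,71.0,42.3,41.8,43.0,9.7,9.4,9.9
male,low,counterfactual_alcohol,70.3,69.0,71.7,42.2,41.7,42.9,9.7,9.4,10.0
male,low,counterfactual_health_literacy,70.7,69.4,72.2,42.2,41.6,42.9,9.8,9.5,10.1
male,low,counterfactual_diet,70.9,69.6,72.4,42.1,41.6,42.8,9.8,9.5,10.1
male,low,counterfactual_joint,66.9,65.5,68.5,42.6,42.1,43.3,9.3,9.1,9.6
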