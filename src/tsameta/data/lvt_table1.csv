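study_id,year,design,outcome,n_int,e_int,n_ctl,e_ctl
McCarthy2019,2019,retrospective_obs,thrombus_resolution,4,4,94,71
Ali2020,2020,retrospective_obs,thrombus_resolution,32,18,60,37
Ali2020,2020,retrospective_obs,stroke,32,2,60,7
Ali2020,2020,retrospective_obs,any_thromboembolism,32,2,60,14
Cochrane2020,2020,retrospective_obs,thrombus_resolution,14,12,59,45
Cochrane2020,2020,retrospective_obs,stroke,14,0,59,9
Cochrane2020,2020,retrospective_obs,any_bleeding,14,2,59,8
Cochrane2020,2020,retrospective_obs,all_cause_death,14,1,59,2
Daher2020,2020,retrospective_obs,thrombus_resolution,17,12,42,30
Daher2020,2020,retrospective_obs,any_thromboembolism,17,2,42,4
Guddeti2020,2020,retrospective_obs,stroke,19,0,80,2
Guddeti2020,2020,retrospective_obs,any_thromboembolism,19,0,80,2
Guddeti2020,2020,retrospective_obs,any_bleeding,19,1,80,4
Iqbal2020,2020,retrospective_obs,thrombus_resolution,22,13,62,42
Iqbal2020,2020,retrospective_obs,stroke,22,0,62,1
Iqbal2020,2020,retrospective_obs,any_thromboembolism,22,0,62,2
Iqbal2020,2020,retrospective_obs,major_bleeding,22,0,62,6
Iqbal2020,2020,retrospective_obs,any_bleeding,22,0,62,6
Iqbal2020,2020,retrospective_obs,all_cause_death,22,3,62,6
Jones2020,2020,prospective_obs,thrombus_resolution,41,34,60,38
Jones2020,2020,prospective_obs,stroke,41,1,60,3
Jones2020,2020,prospective_obs,any_thromboembolism,41,1,60,3
Jones2020,2020,prospective_obs,major_bleeding,41,0,60,7
Jones2020,2020,prospective_obs,any_bleeding,41,6,60,22
Ratnayake2020,2020,retrospective_obs,thrombus_resolution,2,1,42,34
Robinson2020,2020,retrospective_obs,any_thromboembolism,121,17,236,14
Robinson2020,2020,retrospective_obs,any_bleeding,121,8,236,19
Robinson2020,2020,retrospective_obs,all_cause_death,121,14,236,32
Willeford2020,2020,retrospective_obs,thrombus_resolution,22,13,129,63
Willeford2020,2020,retrospective_obs,stroke,22,0,129,7
Willeford2020,2020,retrospective_obs,any_thromboembolism,22,0,129,8
Willeford2020,2020,retrospective_obs,major_bleeding,22,1,129,5
Willeford2020,2020,retrospective_obs,any_bleeding,22,1,129,5
Abdelnabi2021,2021,RCT,thrombus_resolution,39,34,40,32
Abdelnabi2021,2021,RCT,stroke,39,0,40,4
Abdelnabi2021,2021,RCT,any_thromboembolism,39,0,40,6
Abdelnabi2021,2021,RCT,major_bleeding,39,2,40,6
Albabtain2021,2021,retrospective_obs,thrombus_resolution,28,20,35,24
Albabtain2021,2021,retrospective_obs,stroke,28,1,35,1
Albabtain2021,2021,retrospective_obs,any_bleeding,28,2,35,1
Albabtain2021,2021,retrospective_obs,all_cause_death,28,0,35,0
Alcalai2021,2021,RCT,thrombus_resolution,18,17,17,16
Alcalai2021,2021,RCT,stroke,18,0,17,1
Alcalai2021,2021,RCT,any_thromboembolism,18,0,17,1
Alcalai2021,2021,RCT,any_bleeding,18,0,17,2
Alcalai2021,2021,RCT,all_cause_death,18,1,17,0
Bass2021,2021,retrospective_obs,stroke,180,14,769,90
Bass2021,2021,retrospective_obs,any_thromboembolism,180,55,769,254
Bass2021,2021,retrospective_obs,major_bleeding,180,3,769,22
Bass2021,2021,retrospective_obs,any_bleeding,180,14,769,84
Hofer2021,2021,prospective_obs,thrombus_resolution,10,7,33,20
Isa2021,2021,RCT,stroke,14,1,13,0
Isa2021,2021,RCT,major_bleeding,14,0,13,1
Isa2021,2021,RCT,all_cause_death,14,2,13,4
Iskaros2021,2021,retrospective_obs,thrombus_resolution,32,27,45,34
Iskaros2021,2021,retrospective_obs,stroke,32,1,45,0
Iskaros2021,2021,retrospective_obs,any_thromboembolism,32,1,45,0
Iskaros2021,2021,retrospective_obs,any_bleeding,32,1,45,2
Iskaros2021,2021,retrospective_obs,all_cause_death,32,0,45,0
Mihm2021,2021,retrospective_obs,thrombus_resolution,33,14,75,26
Mihm2021,2021,retrospective_obs,stroke,33,2,75,4
Mihm2021,2021,retrospective_obs,any_thromboembolism,33,3,75,4
Mihm2021,2021,retrospective_obs,major_bleeding,33,5,75,2
Mihm2021,2021,retrospective_obs,all_cause_death,33,4,75,6
Varwani2021,2021,retrospective_obs,thrombus_resolution,36,20,25,16
Varwani2021,2021,retrospective_obs,stroke,36,1,25,1
Varwani2021,2021,retrospective_obs,any_bleeding,36,3,25,2
Xu2021,2021,retrospective_obs,thrombus_resolution,25,19,62,46
Xu2021,2021,retrospective_obs,stroke,25,1,62,3
Xu2021,2021,retrospective_obs,any_thromboembolism,25,1,62,4
Xu2021,2021,retrospective_obs,any_bleeding,25,1,62,2
Xu2021,2021,retrospective_obs,all_cause_death,25,2,62,3
Zhang2021,2021,retrospective_obs,thrombus_resolution,33,26,31,23
Zhang2021,2021,retrospective_obs,any_thromboembolism,33,1,31,4
Zhang2021,2021,retrospective_obs,major_bleeding,33,0,31,1
Zhang2021,2021,retrospective_obs,any_bleeding,33,2,31,3
Zhang2021,2021,retrospective_obs,all_cause_death,33,1,31,4
Herald2022,2022,retrospective_obs,stroke,134,26,299,73
Herald2022,2022,retrospective_obs,any_thromboembolism,134,29,299,84
Herald2022,2022,retrospective_obs,any_bleeding,134,37,299,113
Herald2022,2022,retrospective_obs,all_cause_death,134,32,299,138
Rahunathan2022,2022,retrospective_obs,thrombus_resolution,14,6,4,1
Rahunathan2022,2022,retrospective_obs,stroke,14,0,4,0
Rahunathan2022,2022,retrospective_obs,any_thromboembolism,14,0,4,0
Rahunathan2022,2022,retrospective_obs,major_bleeding,14,0,4,0
Zhang2022,2022,retrospective_obs,thrombus_resolution,109,77,78,46
Zhang2022,2022,retrospective_obs,any_thromboembolism,109,5,78,10
Zhang2022,2022,retrospective_obs,major_bleeding,109,0,78,1
Zhang2022,2022,retrospective_obs,any_bleeding,109,8,78,5
Zhang2022,2022,retrospective_obs,all_cause_death,109,31,78,27
Seiler2023,2023,retrospective_obs,thrombus_resolution,48,40,53,37
Seiler2023,2023,retrospective_obs,stroke,48,4,53,4
Seiler2023,2023,retrospective_obs,any_thromboembolism,48,6,53,5
Seiler2023,2023,retrospective_obs,major_bleeding,48,3,53,2
Seiler2023,2023,retrospective_obs,any_bleeding,48,5,53,9
Seiler2023,2023,retrospective_obs,all_cause_death,48,4,53,6
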