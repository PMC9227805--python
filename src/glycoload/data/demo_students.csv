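student_id,sex,age_years,maturation,pa_min_week,bmi_z,diabetes_self_report,stratum,psu,weight,glucose_mg_dl,insulin_mU_L,hba1c_pct
S000001,female,13.8,2,328.0,1.985,0,ST1,ST1-SCH01,1.5751,87.42,11.99,5.86
S000002,female,14.6,2,300.0,-0.841,0,ST1,ST1-SCH01,1.835,75.29,5.8,4.95
S000003,male,15.3,4,0.0,-1.169,0,ST1,ST1-SCH01,0.5866,90.64,10.18,5.55
S000004,female,13.4,2,76.0,1.243,0,ST1,ST1-SCH01,0.8416,75.1,10.0,5.47
S000005,female,12.7,1,132.0,-0.599,0,ST1,ST1-SCH01,1.235,69.08,12.29,4.88
S000006,male,15.9,3,127.0,1.155,0,ST1,ST1-SCH02,1.6061,89.26,13.62,5.94
S000007,female,15.4,3,50.0,4.0,0,ST1,ST1-SCH02,1.1347,97.73,7.27,6.0
S000008,female,14.6,2,0.0,0.48,0,ST1,ST1-SCH02,0.7994,79.46,10.98,5.08
S000009,male,16.1,3,86.0,-0.772,0,ST1,ST1-SCH02,1.0932,90.66,11.73,5.96
S000010,male,14.7,3,574.0,2.012,0,ST1,ST1-SCH02,0.995,87.31,9.34,5.47
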