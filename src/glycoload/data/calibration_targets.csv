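variable,sex,weight_status,value
dgi,female,NW,59.35
dgi,female,OW,59.14
dgi,male,NW,59.53
dgi,male,OW,59.21
av_gi,female,NW,59.17
av_gi,female,OW,59.12
av_gi,male,NW,59.50
av_gi,male,OW,59.18
dgl,female,NW,165.22
dgl,female,OW,140.61
dgl,male,NW,194.86
dgl,male,OW,164.94
av_gl,female,NW,37.92
av_gl,female,OW,34.29
av_gl,male,NW,45.27
av_gl,male,OW,40.63
glucose_mg_dl,female,NW,84.45
glucose_mg_dl,female,OW,85.26
glucose_mg_dl,male,NW,86.80
glucose_mg_dl,male,OW,88.04
hba1c_pct,female,NW,5.33
hba1c_pct,female,OW,5.38
hba1c_pct,male,NW,5.40
hba1c_pct,male,OW,5.42
insulin_mU_L,female,NW,8.71
insulin_mU_L,female,OW,13.20
insulin_mU_L,male,NW,7.10
insulin_mU_L,male,OW,12.04
homa_ir,female,NW,1.84
homa_ir,female,OW,2.82
homa_ir,male,NW,1.54
homa_ir,male,OW,2.66
energy_kcal,all,NW,2372
energy_kcal,all,OW,2059
total_carb_g,all,NW,316
total_carb_g,all,OW,271
fiber_g,all,NW,19
fiber_g,all,OW,16
protein_g,all,NW,93
protein_g,all,OW,84
lipid_g,all,NW,83
lipid_g,all,OW,72
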