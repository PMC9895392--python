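study_id,timing,level,sample_type,country_year,diagnostic_criteria,excludes_confounders,n_case,mean_case,sd_case,n_control,mean_control,sd_control
Tang,late,protein,Serum,"China, 2019","WHO guidelines, 2013",yes,130,114.787,47.627,130,81.381,32.558
Banerjee,late,protein,Serum,"India, 2021","IADPSG criteria, 2018",not_available,23,1091.6,115.4,20,828.5,160.0
Yakut,late,protein,Serum,"Turkey, 2021","ACOG guidelines, 2018",yes,40,1786.347,3176.192,40,283.604,158.833
Jacobsen,late,protein,Serum,"Norway, 2022","WHO guidelines, 2013",yes,35,99036.566,40566.734,269,91134.718,37806.970
Tang,middle,protein,Serum,"China, 2019","WHO guidelines, 2013",yes,200,32.652,14.748,200,30.868,12.732
Banerjee,middle,protein,Serum,"India, 2021","IADPSG criteria, 2018",not_available,12,1002.8,176.3,10,820.5,115.6
Li,middle,protein,Serum,"China, 2020","WHO guidelines, 2013",yes,200,18.462,8.023,211,13.941,5.567
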