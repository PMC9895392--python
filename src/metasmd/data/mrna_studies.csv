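study_id,timing,level,sample_type,country_year,diagnostic_criteria,excludes_confounders,n_case,mean_case,sd_case,n_control,mean_control,sd_control
GSE49524,late,mRNA,Umbilical cord,"Italy, 2013",,not_available,3,11.410,0.470,3,10.965,0.165
GSE70493,late,mRNA,Placental tissue,"America, 2015",,yes,32,10.774,0.356,31,10.708,0.541
GSE65737,late,mRNA,Umbilical cord vein blood,"China, 2015","IADPSG criteria, 2018",yes,30,5.485,0.073,30,5.265,0.232
GSE87295,late,mRNA,Human umbilical vein endothelial cells,"Singapore, 2016",,not_available,5,624.648,281.441,5,2699.146,3743.309
GSE51546,late,mRNA,Umbilical cord,"Finland, 2016",,not_available,6,82.418,16.052,6,75.397,6.509
GSE103552,late,mRNA,Primary feto-placental endothelial cells,"Austria, 2018","IADPSG criteria, 2018",not_available,20,11.975,0.262,17,11.879,0.267
GSE128381,late,mRNA,Placental tissue,"Belgium, 2019",,yes,6,18.405,0.230,177,18.405,0.260
GSE150621,late,mRNA,Amniocytes,"America, 2020",,not_available,6,4191.167,2453.229,8,3681.250,2649.155
GSE154377,late,mRNA,Blood,"America, 2020","ACOG guidelines, 2018",yes,6,4.167,3.976,9,1.778,1.787
GSE154377,middle,mRNA,Blood,"America, 2020","ACOG guidelines, 2018",yes,7,0.714,0.951,9,1.333,2.958
GSE154414,late,mRNA,Placental tissue,"China, 2021",,not_available,4,844.421,221.869,4,643.824,31.750
GSE194119,late,mRNA,Cord blood,"China, 2022",,not_available,3,1.351,0.830,3,1.657,0.663
GSE203346,late,mRNA,Placental tissue,"Norway, 2022","IADPSG criteria, 2018",yes,21,4.885,1.198,20,3.650,1.885
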