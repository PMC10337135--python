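# Published period-total burden attributable to overweight, Chile 2019-2030,
# by outcome (cases|deaths), disease and scenario (BAU|S1|S2|S3), with the
# printed 95% CIs. TOTAL_CANCER rows are the printed cancer subtotals.
# Repairs (flag column non-empty):
#   repaired_value cases/cirrhosis/BAU: printed "1,.630"; 14,630 is the unique
#     value making the BAU column sum equal the printed total 669,100 and is
#     consistent with the neighbouring scenario values 14,439/14,359/14,046.
#   repaired_value cases/stroke/S2: printed "78,.493"; 78,493 by the same
#     column-sum identity against the printed Scenario-2 total 659,010.
#   repaired_ci cases/chronic_kidney_disease/BAU ci_low: printed "159,46";
#     stored as 159,460 (best reading; nothing downstream uses CIs).
#   repaired_ci deaths/stroke/S3 ci_low: printed "23.,91"; stored as 23,991
#     (best reading consistent with the neighbouring scenario bounds).
outcome,disease_id,scenario,value,ci_low,ci_high,flag
cases,coronary_heart_disease,BAU,53463,49543,57741,
cases,coronary_heart_disease,S1,52729,48862,56947,
cases,coronary_heart_disease,S2,52432,48587,56626,
cases,coronary_heart_disease,S3,50877,47146,54947,
cases,stroke,BAU,79859,68969,92564,
cases,stroke,S1,78889,68131,91439,
cases,stroke,S2,78493,67789,90981,repaired_value
cases,stroke,S3,76499,66067,88670,
cases,hypertensive_heart_disease,BAU,9091,7837,10569,
cases,hypertensive_heart_disease,S1,9008,7766,10473,
cases,hypertensive_heart_disease,S2,8974,7736,10433,
cases,hypertensive_heart_disease,S3,8796,7583,10226,
cases,type2_diabetes,BAU,302103,264342,344064,
cases,type2_diabetes,S1,299371,261952,340953,
cases,type2_diabetes,S2,298243,260965,339669,
cases,type2_diabetes,S3,292819,256219,333491,
cases,chronic_kidney_disease,BAU,199638,159460,249870,repaired_ci
cases,chronic_kidney_disease,S1,197349,157636,247005,
cases,chronic_kidney_disease,S2,196416,158910,245837,
cases,chronic_kidney_disease,S3,191547,153002,239743,
cases,cirrhosis,BAU,14630,12587,17001,repaired_value
cases,cirrhosis,S1,14439,12422,16778,
cases,cirrhosis,S2,14359,12350,16685,
cases,cirrhosis,S3,14046,12085,16322,
cases,colorectal_cancer,BAU,4819,4657,4980,
cases,colorectal_cancer,S1,4757,4597,4916,
cases,colorectal_cancer,S2,4709,4551,4866,
cases,colorectal_cancer,S3,4444,4295,4593,
cases,kidney_cancer,BAU,1060,985,1140,
cases,kidney_cancer,S1,1047,974,1126,
cases,kidney_cancer,S2,1038,965,1116,
cases,kidney_cancer,S3,984,915,1058,
cases,liver_cancer,BAU,1466,1256,1705,
cases,liver_cancer,S1,1450,1243,1687,
cases,liver_cancer,S2,1438,1233,1673,
cases,liver_cancer,S3,1370,1174,1593,
cases,breast_cancer,BAU,1860,1790,1926,
cases,breast_cancer,S1,1839,1773,1905,
cases,breast_cancer,S2,1822,1757,1887,
cases,breast_cancer,S3,1731,1669,1793,
cases,pancreatic_cancer,BAU,1111,1081,1152,
cases,pancreatic_cancer,S1,1097,1067,1137,
cases,pancreatic_cancer,S2,1086,1057,1126,
cases,pancreatic_cancer,S3,1022,994,1059,
cases,TOTAL_CANCER,BAU,10316,9770,10903,
cases,TOTAL_CANCER,S1,10190,9654,10771,
cases,TOTAL_CANCER,S2,10093,9563,10668,
cases,TOTAL_CANCER,S3,9551,9047,10096,
deaths,coronary_heart_disease,BAU,32303,29934,34887,
deaths,coronary_heart_disease,S1,31860,29523,34408,
deaths,coronary_heart_disease,S2,31681,29358,34216,
deaths,coronary_heart_disease,S3,30777,28520,33239,
deaths,stroke,BAU,28896,24956,33493,
deaths,stroke,S1,28528,24638,33067,
deaths,stroke,S2,28379,24509,32894,
deaths,stroke,S3,27663,23991,32064,repaired_ci
deaths,hypertensive_heart_disease,BAU,7494,6461,8713,
deaths,hypertensive_heart_disease,S1,7424,6400,8631,
deaths,hypertensive_heart_disease,S2,7396,6376,8598,
deaths,hypertensive_heart_disease,S3,7249,6249,8427,
deaths,type2_diabetes,BAU,21796,19071,24823,
deaths,type2_diabetes,S1,21580,18883,24577,
deaths,type2_diabetes,S2,21492,18806,24478,
deaths,type2_diabetes,S3,21082,18447,24011,
deaths,chronic_kidney_disease,BAU,9606,7673,12023,
deaths,chronic_kidney_disease,S1,9476,7569,11860,
deaths,chronic_kidney_disease,S2,9424,7527,11795,
deaths,chronic_kidney_disease,S3,9174,7328,11482,
deaths,cirrhosis,BAU,10514,9046,12218,
deaths,cirrhosis,S1,10373,8924,12054,
deaths,cirrhosis,S2,10314,8873,11985,
deaths,cirrhosis,S3,10086,8677,11720,
deaths,colorectal_cancer,BAU,3122,3017,3226,
deaths,colorectal_cancer,S1,3081,2978,3184,
deaths,colorectal_cancer,S2,3050,2948,3152,
deaths,colorectal_cancer,S3,2883,2786,2979,
deaths,kidney_cancer,BAU,805,748,866,
deaths,kidney_cancer,S1,795,739,855,
deaths,kidney_cancer,S2,788,732,847,
deaths,kidney_cancer,S3,748,695,804,
deaths,liver_cancer,BAU,1343,1151,1562,
deaths,liver_cancer,S1,1329,1139,1546,
deaths,liver_cancer,S2,1318,1129,1533,
deaths,liver_cancer,S3,1255,1076,1460,
deaths,breast_cancer,BAU,464,447,480,
deaths,breast_cancer,S1,458,442,475,
deaths,breast_cancer,S2,454,438,470,
deaths,breast_cancer,S3,431,416,447,
deaths,pancreatic_cancer,BAU,1005,978,1042,
deaths,pancreatic_cancer,S1,993,966,1029,
deaths,pancreatic_cancer,S2,983,956,1019,
deaths,pancreatic_cancer,S3,927,801,960,
deaths,TOTAL_CANCER,BAU,6739,6341,7176,
deaths,TOTAL_CANCER,S1,6656,6264,7089,
deaths,TOTAL_CANCER,S2,6593,6203,7021,
deaths,TOTAL_CANCER,S3,6244,5953,6650,
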