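patient_id,age_years,er_status,allred_score,histologic_grade,days_to_post_mri
1,41,negative,,2,16
2,39,negative,,3,11
3,37,negative,,3,14
4,57,negative,,2,14
5,40,negative,,3,18
6,60,negative,,1,14
7,61,negative,,3,11
8,53,positive,3,2,21
9,47,positive,4,3,15
10,37,positive,7,3,28
11,64,positive,8,2,14
12,69,positive,8,3,36
13,51,positive,8,3,14
14,52,positive,8,2,14
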