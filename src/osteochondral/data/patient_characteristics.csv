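patient_id,age_years,sex,bmi_kg_m2,rheumatoid_arthritis,mean_oarsi,operated_knee
1,57,F,35.6,no,3.4,both
2,61,F,36.1,no,3.7,left
3,79,M,27.8,no,4.3,right
4,87,F,22.3,no,5.1,right
5,78,F,27.6,spondylarthritis,4.2,left
6,83,F,26.5,no,4.3,right
7,78,F,28.7,no,3.9,left
8,88,F,30.2,no,3.8,right
9,84,F,25.0,no,4.4,right
10,76,F,25.9,no,3.6,right_medial
11,84,F,34.4,no,4.2,left
12,77,M,26.0,no,4.0,right
13,66,F,26.2,no,4.1,right
14,61,F,33.3,no,4.4,both
15,75,F,34.1,no,4.6,both
16,62,F,30.2,no,4.7,left
17,61,F,33.3,no,4.0,both
18,81,F,34.6,yes,3.4,right
19,70,M,36.1,no,3.7,left
20,82,F,30.4,no,3.6,right
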