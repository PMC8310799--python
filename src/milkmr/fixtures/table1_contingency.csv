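cohort,panel,row,n_never,n_drinker,pct_never,pct_drinker
1958bc,gender,men,846,2106,28.66,71.34
1958bc,gender,women,855,1636,34.32,65.68
uk_biobank,gender,men,11519,175071,6.17,93.83
uk_biobank,gender,women,20212,199131,9.21,90.79
1958bc,bmi,underweight,10,17,37.04,62.96
1958bc,bmi,normal,571,1232,31.67,68.33
1958bc,bmi,overweight,702,1597,30.54,69.46
1958bc,bmi,obese,416,893,31.78,68.22
uk_biobank,bmi,underweight,307,1718,15.16,84.84
uk_biobank,bmi,normal,12550,119030,9.54,90.46
uk_biobank,bmi,overweight,12129,160852,7.01,92.99
uk_biobank,bmi,obese,6612,91450,6.74,93.26
1958bc,lct_additive,TT,917,2110,30.29,69.71
1958bc,lct_additive,CT,657,1397,31.99,68.01
1958bc,lct_additive,CC,127,234,35.18,64.82
uk_biobank,lct_additive,TT,17287,207963,7.67,92.33
uk_biobank,lct_additive,CT,11108,131163,7.81,92.19
uk_biobank,lct_additive,CC,2090,20820,9.12,90.88
1958bc,lct_recessive,TT+CT,1574,3507,30.98,69.02
1958bc,lct_recessive,CC,127,234,35.18,64.82
uk_biobank,lct_recessive,TT+CT,28395,339126,7.73,92.27
uk_biobank,lct_recessive,CC,2090,20820,9.12,90.88
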