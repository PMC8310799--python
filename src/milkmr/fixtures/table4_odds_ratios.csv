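source,phenotype,n_cases,n_controls,odds_ratio,ci_low,ci_high,p
diagram,type_2_diabetes,34840,114981,1.06,0.97,1.16,0.201
cardiogram,coronary_artery_disease,22233,64762,0.86,0.75,0.99,0.030
uk_biobank,type_2_diabetes,20820,351375,0.89,0.82,0.97,0.007
uk_biobank,cardiovascular_disease,42317,332930,0.97,0.92,1.03,0.302
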