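study,trait,kind,beta,se,n
uk_biobank,bmi,phenotypic,0.146,0.006,404648
1958bc,bmi,phenotypic,-0.015,0.029,5438
uk_biobank,bmi,genetic,0.014,0.003,375247
1958bc,bmi,genetic,0.0005,0.021,5672
hrs,bmi,genetic,-0.008,0.018,8445
consortia,bmi,genetic,0.016,0.003,311359
uk_biobank,wc,phenotypic,-0.000003,0.004,404571
1958bc,wc,phenotypic,-0.016,0.021,5424
uk_biobank,wc,genetic,-0.001,0.002,375174
1958bc,wc,genetic,-0.012,0.015,5656
hrs,wc,genetic,0.011,0.02,4684
consortia,wc,genetic,0.01,0.004,223634
uk_biobank,sbp,phenotypic,0.56,0.11,369133
1958bc,sbp,phenotypic,-0.39,0.45,5421
uk_biobank,sbp,genetic,-0.0058,0.052,342729
1958bc,sbp,genetic,0.28,0.33,5654
hrs,sbp,genetic,0.26,0.66,4694
consortia,sbp,genetic,0.008,0.036,697305
uk_biobank,dbp,phenotypic,0.17,0.064,369142
1958bc,dbp,phenotypic,-0.45,0.30,5421
uk_biobank,dbp,genetic,0.040,0.029,342737
1958bc,dbp,genetic,0.18,0.22,5654
hrs,dbp,genetic,0.29,0.39,4694
consortia,dbp,genetic,0.025,0.021,697307
uk_biobank,hdl_c,phenotypic,-0.024,0.005,352898
1958bc,hdl_c,phenotypic,-0.051,0.030,5334
uk_biobank,hdl_c,genetic,-0.015,0.002,327286
1958bc,hdl_c,genetic,-0.037,0.022,5563
hrs,hdl_c,genetic,0.013,0.029,3553
consortia,hdl_c,genetic,-0.014,0.004,183570
uk_biobank,ldl_c,phenotypic,0.055,0.006,384881
1958bc,ldl_c,phenotypic,-0.045,0.030,5033
uk_biobank,ldl_c,genetic,-0.023,0.003,356937
1958bc,ldl_c,genetic,-0.030,0.022,5247
consortia,ldl_c,genetic,-0.028,0.004,169531
uk_biobank,total_cholesterol,phenotypic,0.042,0.006,385586
1958bc,total_cholesterol,phenotypic,-0.054,0.029,5341
uk_biobank,total_cholesterol,genetic,-0.027,0.003,357601
1958bc,total_cholesterol,genetic,-0.055,0.021,5570
hrs,total_cholesterol,genetic,0.003,0.026,4228
consortia,total_cholesterol,genetic,-0.031,0.004,183761
uk_biobank,triglycerides,phenotypic,0.049,0.006,385287
1958bc,triglycerides,phenotypic,0.016,0.026,5330
uk_biobank,triglycerides,genetic,0.001,0.003,357317
1958bc,triglycerides,genetic,-0.051,0.019,5559
consortia,triglycerides,genetic,-0.003,0.004,174267
uk_biobank,hba1c,phenotypic,0.020,0.003,385644
1958bc,hba1c,phenotypic,0.006,0.015,5339
uk_biobank,hba1c,genetic,-0.002,0.001,357767
1958bc,hba1c,genetic,-0.002,0.011,5568
hrs,hba1c,genetic,0.011,0.017,4408
consortia,hba1c,genetic,-0.0001,0.002,123665
uk_biobank,crp,phenotypic,0.069,0.006,384759
1958bc,crp,phenotypic,0.042,0.027,5276
uk_biobank,crp,genetic,0.002,0.003,356829
1958bc,crp,genetic,0.03,0.02,5503
hrs,crp,genetic,0.003,0.027,4246
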