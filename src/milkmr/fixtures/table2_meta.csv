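trait,kind,beta,se,p,het_p,i2,w_uk_biobank,w_1958bc,w_hrs,w_consortia
bmi,phenotypic,0.068,0.08,0.40,5.60E-08,96.6,51.55,48.45,,
bmi,genetic,0.015,0.002,4.68E-12,0.64,0,61.6,,,38.4
wc,phenotypic,-0.0007,0.004,0.88,0.45,0,95.99,4.01,,
wc,genetic,0.004,0.006,0.49,0.007,86.2,53.81,,,46.19
sbp,phenotypic,0.18,0.47,0.69,0.04,76.4,60.35,39.65,,
sbp,genetic,0.0085,0.035,0.81,0.71,0,,,0.29,99.71
dbp,phenotypic,-0.071,0.30,0.81,0.05,74.9,61.48,38.52,,
dbp,genetic,0.026,0.021,0.21,0.51,0,,,0.28,99.72
hdl_c,phenotypic,-0.025,0.005,2.70E-06,0.37,0,96.8,3.2,,
hdl_c,genetic,-0.015,0.002,9.40E-13,0.59,0,71.38,,0.5,28.12
ldl_c,phenotypic,0.009,0.050,0.86,0.0009,90.85,54.21,,,
ldl_c,genetic,-0.024,0.002,2.08E-26,0.32,0,70.38,,,29.62
total_cholesterol,phenotypic,-0.002,0.048,0.96,0.001,90.67,54.28,45.72,,
total_cholesterol,genetic,-0.028,0.002,2.40E-36,0.38,0,67.99,,0.72,31.3
triglycerides,phenotypic,0.043,0.013,0.001,0.22,34.36,79.98,20.02,,
triglycerides,genetic,0.00007,0.002,0.97,0.32,0.87,69.22,,,30.78
hba1c,phenotypic,0.019,0.003,1.10E-13,0.38,0,97.04,2.96,,
hba1c,genetic,-0.001,0.001,0.27,0.61,0,67.66,,0.38,31.95
crp,phenotypic,0.068,0.006,2.60E-30,0.31,1.56,95.04,4.96,,
crp,genetic,0.002,0.002,0.42,0.37,0,97.55,1.6,0.85,
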