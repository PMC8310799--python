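trait,kind,n,beta,se,p
total_body_fat,phenotypic,398654,0.086,0.005,8.38E-76
total_body_fat,genetic,369696,0.011,0.002,1.63E-07
total_body_fat,iv_ratio,369696,0.031,0.009,2.40E-04
leg_fat,phenotypic,398853,0.078,0.004,1.59E-95
leg_fat,genetic,369879,0.009,0.002,2.18E-07
leg_fat,iv_ratio,369879,0.025,0.007,2.59E-04
arm_fat,phenotypic,398799,0.084,0.005,1.46E-71
arm_fat,genetic,369834,0.010,0.002,1.37E-06
arm_fat,iv_ratio,369834,0.029,0.008,4.27E-04
trunk_fat,phenotypic,398639,0.095,0.006,1.67E-64
trunk_fat,genetic,369683,0.012,0.002,3.92E-07
trunk_fat,iv_ratio,369683,0.036,0.01,3.01E-04
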