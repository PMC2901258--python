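clade,lam,lam_ci_lo,lam_ci_hi,mu,mu_ci_lo,mu_ci_hi,epsilon,mean_rate,mean_rate_hpd_lo,mean_rate_hpd_hi,rate_cv,rate_cv_hpd_lo,rate_cv_hpd_hi
Antirrhineae,1.070,0.716,1.588,0.989,0.602,1.533,0.924,8.10E-03,6.24E-03,1.02E-02,0.547,0.367,0.737
Artemisia,0.379,0.275,0.516,0.239,0.106,0.401,0.631,1.69E-03,1.24E-03,2.20E-03,0.921,0.697,1.180
Chironiinae,0.456,0.292,0.702,0.350,0.133,0.637,0.769,6.32E-03,4.45E-03,8.45E-03,0.422,0.245,0.601
Ericameria,0.234,0.170,0.342,0,0,0.166,0,2.17E-03,1.01E-03,3.82E-03,0.809,0.422,1.214
Lepidium,0.956,0.670,1.350,0.589,0.175,1.086,0.617,8.26E-03,5.25E-03,1.18E-02,0.753,0.512,1.016
Lotus,0.366,0.259,0.515,0.330,0.205,0.492,0.902,2.78E-03,1.93E-03,3.69E-03,0.722,0.514,0.944
Lupinus,1.547,1.112,2.139,1.388,0.900,2.023,0.898,2.18E-03,1.26E-03,3.28E-03,1.060,0.554,1.631
Lycieae,0.177,0.136,0.292,0,0,0.163,0,2.80E-03,1.97E-03,3.70E-03,0.497,0.246,0.758
Phrymoideae,0.265,0.185,0.375,0.188,0.079,0.320,0.709,6.22E-03,4.79E-03,7.72E-03,0.632,0.487,0.790
Polemoniaceae,0.318,0.254,0.396,0.227,0.145,0.321,0.715,5.15E-03,4.25E-03,6.11E-03,0.551,0.450,0.656
Salvia,1.649,1.181,2.282,1.466,0.957,2.134,0.889,6.56E-03,5.13E-03,8.04E-03,0.614,0.477,0.760
Saniculoideae,0.259,0.194,0.345,0.164,0.073,0.269,0.631,1.78E-03,1.30E-03,2.27E-03,0.611,0.442,0.794
Sidalcea,0.053,0.039,0.095,0,0,0.061,0,1.21E-03,9.34E-04,1.52E-03,0.667,0.419,0.959
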