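id,ploec,ploec_change_pct,log_t_half,log_t_half_change_pct,log_kow,log_kow_change_pct
PAZ,7.048,,1.789,,1.140,
Derivative-1,7.404,5.05,1.925,7.60,0.191,-83.25
Derivative-2,7.575,7.48,1.954,9.22,0.140,-87.72
Derivative-3,7.322,3.89,1.937,8.27,0.289,-74.65
Derivative-4,6.930,-1.67,1.934,8.11,1.689,48.16
Derivative-5,6.936,-1.59,1.869,4.47,1.602,40.53
Derivative-6,6.777,-3.85,1.926,7.66,1.254,10.00
Derivative-7,7.082,0.48,1.726,-3.52,1.169,2.54
Derivative-8,7.203,2.20,1.821,1.79,1.631,43.07
Derivative-9,7.073,0.35,1.728,-3.41,1.354,18.77
Derivative-10,7.089,0.58,1.744,-2.52,1.113,-2.37
Derivative-11,7.031,-0.24,1.732,-3.19,1.170,2.63
Derivative-12,7.033,-0.21,1.954,9.22,1.126,-1.23
Derivative-13,7.022,-0.37,1.827,2.12,1.856,62.81
Derivative-14,7.009,-0.55,1.555,-13.08,2.623,130.09
Derivative-15,7.048,0.00,1.987,11.07,2.083,82.72
Derivative-16,7.061,0.18,1.831,2.35,1.848,62.11
Derivative-17,6.993,-0.78,1.930,7.88,1.907,67.28
Derivative-18,7.007,-0.58,1.862,4.08,2.102,84.39
Derivative-19,7.193,2.06,1.860,3.97,1.629,42.89
Derivative-20,7.245,2.80,1.942,8.55,2.108,84.91
Derivative-21,7.185,1.94,1.862,4.08,1.794,57.37
Derivative-22,7.129,1.15,1.952,9.11,1.768,55.09
Derivative-23,7.121,1.04,1.969,10.06,1.545,35.53
Derivative-24,7.173,1.77,1.877,4.92,1.639,43.77
Derivative-25,7.030,-0.26,2.028,13.36,2.055,80.26
Derivative-26,7.034,-0.20,2.073,15.87,2.254,97.72
Derivative-27,7.051,0.04,1.978,10.56,2.087,83.07
Derivative-28,7.033,-0.21,1.837,2.68,1.875,64.47
Derivative-29,6.988,-0.85,1.956,9.33,2.085,82.89
Derivative-30,7.055,0.10,1.847,3.24,1.917,68.16
Derivative-31,6.987,-0.87,1.903,6.37,2.317,103.25
Derivative-32,6.938,-1.56,1.414,-20.96,2.378,108.60
Derivative-33,6.743,-4.33,1.769,-1.12,2.599,127.98
Derivative-34,7.253,2.91,1.438,-19.62,0.486,-57.37
Derivative-35,7.242,2.75,1.941,8.50,2.403,110.79
Derivative-36,7.293,3.48,1.939,8.38,2.330,104.39
Derivative-37,7.123,1.06,1.884,5.31,2.205,93.42
Derivative-38,6.949,-1.40,1.709,-4.47,2.515,120.61
Derivative-39,6.922,-1.79,2.060,15.15,2.352,106.32
Derivative-40,6.884,-2.33,1.749,-2.24,2.215,94.30
Derivative-41,7.056,0.11,1.854,3.63,1.959,71.84
Derivative-42,7.076,0.40,1.942,8.55,2.184,91.58
Derivative-43,7.180,1.87,1.880,5.09,1.580,38.60
Derivative-44,7.057,0.13,1.870,4.53,1.960,71.93
Derivative-45,7.149,1.43,1.864,4.19,1.535,34.65
Derivative-46,7.155,1.52,1.953,9.17,1.614,41.58
Derivative-47,6.953,-1.35,1.767,-1.23,1.919,68.33
Derivative-48,7.152,1.48,1.921,7.38,1.669,46.40
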