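parent,id,pred59,pred59_change_pct,pred61,pred61_change_pct,pred_avg,pred_avg_change_pct
PAZ,PAZ,,,,,7.048,
PAZ,PAZ-Cl-1,7.448,5.68,7.992,13.39,7.720,9.53
PAZ,PAZ-Cl-2,7.719,9.52,8.113,15.11,7.916,12.32
PAZ,PAZ-Cl-3,7.806,10.75,7.991,13.38,7.899,12.07
PAZ,PAZ-Cl-4,7.588,7.66,8.195,16.27,7.891,11.96
PAZ,PAZ-Cl-5,7.378,4.68,7.755,10.03,7.567,7.36
PAZ,PAZ-Cl-6,7.275,3.22,7.678,8.94,7.477,6.09
PAZ,PAZ-Cl-7,7.149,1.43,7.533,6.88,7.341,4.16
PAZ,PAZ-Cl-8,6.967,-1.15,7.235,2.65,7.101,0.75
PAZ,PAZ-Cl-9,6.829,-3.11,7.355,4.36,7.092,0.62
PAZ,PAZ-Cl-10,7.497,6.37,7.709,9.38,7.603,7.87
PAZ,PAZ-Cl-11,7.481,6.14,7.670,8.83,7.575,7.48
PAZ,PAZ-Cl-12,7.415,5.21,7.649,8.53,7.532,6.87
PAZ,PAZ-Cl-13,7.375,4.64,7.572,7.43,7.473,6.03
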