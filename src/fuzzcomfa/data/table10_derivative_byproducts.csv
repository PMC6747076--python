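parent,id,pred59,pred59_change_pct,pred61,pred61_change_pct,pred_avg,pred_avg_change_pct
Derivative-1,Derivative-1,,,,,7.404,
Derivative-1,Derivative-1-Cl-1,7.335,-0.93,7.907,6.79,7.621,2.93
Derivative-1,Derivative-1-Cl-2,7.439,0.47,7.745,4.61,7.592,2.54
Derivative-1,Derivative-1-Cl-3,7.523,1.61,7.615,2.85,7.569,2.23
Derivative-1,Derivative-1-Cl-4,7.162,-3.27,7.466,0.84,7.314,-1.22
Derivative-1,Derivative-1-Cl-5,6.506,-12.13,6.524,-11.89,6.515,-12.01
Derivative-1,Derivative-1-Cl-6,6.815,-7.96,7.227,-2.39,7.021,-5.17
Derivative-1,Derivative-1-Cl-7,6.823,-7.85,7.200,-2.76,7.011,-5.31
Derivative-1,Derivative-1-Cl-8,7.125,-3.77,7.181,-3.01,7.153,-3.39
Derivative-1,Derivative-1-Cl-9,7.076,-4.43,7.119,-3.85,7.097,-4.15
Derivative-1,Derivative-1-Cl-10,7.012,-5.29,7.100,-4.11,7.056,-4.70
Derivative-1,Derivative-1-Cl-11,7.027,-5.09,7.024,-5.13,7.025,-5.12
Derivative-2,Derivative-2,,,,,7.575,
Derivative-2,Derivative-2-Cl-1,7.049,-6.94,7.399,-2.32,7.224,-4.63
Derivative-2,Derivative-2-Cl-2,7.145,-5.68,7.293,-3.72,7.219,-4.70
Derivative-2,Derivative-2-Cl-3,7.246,-4.34,7.167,-5.39,7.207,-4.86
Derivative-2,Derivative-2-Cl-4,6.506,-14.11,6.524,-13.87,6.515,-13.99
Derivative-2,Derivative-2-Cl-5,6.815,-10.03,7.227,-4.59,7.021,-7.31
Derivative-2,Derivative-2-Cl-6,6.823,-9.93,7.200,-4.95,7.011,-7.45
Derivative-2,Derivative-2-Cl-7,7.125,-5.94,7.181,-5.20,7.153,-5.57
Derivative-2,Derivative-2-Cl-8,7.076,-6.59,7.119,-6.02,7.097,-6.31
Derivative-2,Derivative-2-Cl-9,7.012,-7.43,7.100,-6.27,7.056,-6.85
Derivative-2,Derivative-2-Cl-10,7.027,-7.23,7.024,-7.27,7.025,-7.26
Derivative-3,Derivative-3,,,,,7.322,
Derivative-3,Derivative-3-Cl-1,7.396,1.01,7.951,8.59,7.674,4.81
Derivative-3,Derivative-3-Cl-2,7.493,2.34,7.811,6.68,7.652,4.51
Derivative-3,Derivative-3-Cl-3,7.578,3.50,7.683,4.93,7.630,4.21
Derivative-3,Derivative-3-Cl-4,7.162,-2.19,7.466,1.97,7.314,-0.11
Derivative-3,Derivative-3-Cl-5,6.506,-11.14,6.524,-10.90,6.515,-11.02
Derivative-3,Derivative-3-Cl-6,6.815,-6.92,7.227,-1.30,7.021,-4.11
Derivative-3,Derivative-3-Cl-7,6.823,-6.82,7.200,-1.67,7.011,-4.25
Derivative-3,Derivative-3-Cl-8,7.125,-2.69,7.181,-1.93,7.153,-2.31
Derivative-3,Derivative-3-Cl-9,7.076,-3.36,7.119,-2.77,7.097,-3.07
Derivative-3,Derivative-3-Cl-10,7.012,-4.23,7.100,-3.03,7.056,-3.63
Derivative-3,Derivative-3-Cl-11,7.027,-4.03,7.024,-4.07,7.025,-4.06
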