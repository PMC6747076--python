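id,cei,cei_change_pct,convulsive,convulsive_change_pct,convulsive_weighted_pct,convulsive_relerr_pct,gastrointestinal,gastrointestinal_change_pct,gastrointestinal_weighted_pct,gastrointestinal_relerr_pct,cardiotoxicity,cardiotoxicity_change_pct,cardiotoxicity_weighted_pct,cardiotoxicity_relerr_pct
PAZ,0.925,,74.075,,,,99.890,,,,93.715,,,
Derivative-1,0.619,-33.08,62.218,-16.01,-16.54,3.23,87.029,-12.88,-13.23,2.70,91.282,-2.60,-3.31,15.07
Derivative-2,0.578,-37.51,60.048,-18.94,-18.76,0.96,85.286,-14.62,-15.01,2.57,91.352,-2.52,-3.75,32.78
Derivative-3,0.649,-29.84,63.499,-14.28,-14.92,4.30,88.230,-11.67,-11.94,2.20,91.266,-2.61,-2.98,12.42
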