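id,name,cei_pred,relative_change_pct
PAZ,PAZ,0.925,
Derivative-1,1-Methyl-PAZ,0.619,-33.08
Derivative-2,1-Hydrogen-PAZ,0.578,-37.51
Derivative-3,1-Ethyl-PAZ,0.649,-29.84
Derivative-4,1-Vinyl-PAZ,0.660,-28.65
Derivative-5,1-Ethynyl-PAZ,0.719,-22.27
Derivative-6,1-Carbonyl-PAZ,0.792,-14.38
Derivative-7,5-Hydroxyl-PAZ,0.879,-4.97
Derivative-8,5-Carboxyl-PAZ,0.827,-10.59
Derivative-9,5-Sulfur-PAZ,0.848,-8.32
Derivative-10,5-Fluorine-PAZ,0.814,-12.00
Derivative-11,5-Chlorine-PAZ,0.717,-22.49
Derivative-12,5-Bromine-PAZ,0.726,-21.51
Derivative-13,1-Methyl-5-Hydroxyl-PAZ,0.762,-17.62
Derivative-14,1-Methyl-5-Carboxyl-PAZ,0.743,-19.68
Derivative-15,1-Methyl-5-Sulfur-PAZ,0.778,-15.89
Derivative-16,1-Methyl-5-Fluorine-PAZ,0.715,-22.70
Derivative-17,1-Methyl-5-Chlorine-PAZ,0.743,-19.68
Derivative-18,1-Methyl-5-Bromine-PAZ,0.775,-16.22
Derivative-19,1-Hydrogen-5-Hydroxyl-PAZ,0.652,-29.51
Derivative-20,1-Hydrogen-5-Carboxyl-PAZ,0.592,-36.00
Derivative-21,1-Hydrogen-5-Sulfur-PAZ,0.641,-30.70
Derivative-22,1-Hydrogen-5-Fluorine-PAZ,0.549,-40.65
Derivative-23,1-Hydrogen-5-Chlorine-PAZ,0.637,-31.14
Derivative-24,1-Hydrogen-5-Bromine-PAZ,0.659,-28.76
Derivative-25,1-Ethyl-5-Hydroxyl-PAZ,0.754,-18.49
Derivative-26,1-Ethyl-5-Carboxyl-PAZ,0.796,-13.95
Derivative-27,1-Ethyl-5-Sulfur-PAZ,0.776,-16.11
Derivative-28,1-Ethyl-5-Fluorine-PAZ,0.727,-21.41
Derivative-29,1-Ethyl-5-Chlorine-PAZ,0.828,-10.49
Derivative-30,1-Ethyl-5-Bromine-PAZ,0.732,-20.86
Derivative-31,1-Vinyl-5-Hydroxyl-PAZ,0.677,-26.81
Derivative-32,1-Vinyl-5-Carboxyl-PAZ,0.613,-33.73
Derivative-33,1-Vinyl-5-Sulfur-PAZ,0.710,-23.24
Derivative-34,1-Vinyl-5-Fluorine-PAZ,0.691,-25.30
Derivative-35,1-Vinyl-5-Chlorine-PAZ,0.558,-39.68
Derivative-36,1-Vinyl-5-Bromine-PAZ,0.454,-50.92
Derivative-37,1-Ethynyl-5-Hydroxyl-PAZ,0.659,-28.76
Derivative-38,1-Ethynyl-5-Carboxyl-PAZ,0.880,-4.86
Derivative-39,1-Ethynyl-5-Sulfur-PAZ,0.875,-5.41
Derivative-40,1-Ethynyl-5-Fluorine-PAZ,0.742,-19.78
Derivative-41,1-Ethynyl-5-Chlorine-PAZ,0.800,-13.51
Derivative-42,1-Ethynyl-5-Bromine-PAZ,0.636,-31.24
Derivative-43,1-Carbonyl-5-Hydroxyl-PAZ,0.718,-22.38
Derivative-44,1-Carbonyl-5-Carboxyl-PAZ,0.682,-26.27
Derivative-45,1-Carbonyl-5-Sulfur-PAZ,0.574,-37.95
Derivative-46,1-Carbonyl-5-Fluorine-PAZ,0.600,-35.14
Derivative-47,1-Carbonyl-5-Chlorine-PAZ,0.758,-18.05
Derivative-48,1-Carbonyl-5-Bromine-PAZ,0.633,-31.57
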