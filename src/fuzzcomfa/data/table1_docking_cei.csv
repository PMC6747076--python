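no,compound,3IP9,3N8V,2L0W,cei
1,Difloxacin,62.686,97.120,65.403,0.687
2,Enrofloxacin,64.070,90.401,90.476,0.707
3,Norfloxacin,58.422,90.557,88.709,0.601
4,Lomefloxacin,68.236,91.137,80.276,0.762
5,Ofloxacin,66.638,86.122,86.940,0.697
6,Pefloxacin,57.529,99.215,92.037,0.689
7,Fleroxacin,66.948,99.890,83.403,0.843
8,Ciprofloxacin,60.930,92.373,86.780,0.661
9,Balofloxacin,49.203,71.254,56.908,0.137
10,Marbofloxacin,65.300,95.242,88.670,0.777
11,Pipemidic acid,62.866,97.025,89.229,0.754
12,Cinoxacin,55.950,90.199,85.239,0.543
13,Enoxacin,60.660,86.605,87.601,0.596
14,Danofloxacin,67.775,91.772,93.715,0.797
15,Gatifloxacin,53.617,63.247,64.941,0.152
16,Levofloxacin,66.638,86.122,86.940,0.697
17,Rufloxacin,62.386,70.009,76.275,0.415
18,Pazufloxacin,74.075,94.849,86.206,0.925
19,Nadifloxacin,56.928,82.392,73.634,0.444
20,Moxifloxacin,46.442,73.108,73.101,0.152
21,Sparfloxacin,60.872,84.400,85.512,0.570
22,Sarafloxacin,59.595,82.206,72.443,0.487
23,Amifloxacin,59.512,86.682,80.072,0.555
24,Besifloxacin,55.541,79.981,76.735,0.401
25,Clinafloxacin,59.317,86.327,80.656,0.549
26,Grepafloxacin,66.245,90.285,93.474,0.753
27,Orbifloxacin,62.945,81.585,84.843,0.575
28,Sitafloxacin,60.702,72.267,83.135,0.428
29,Temafloxacin,66.934,88.733,75.241,0.699
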