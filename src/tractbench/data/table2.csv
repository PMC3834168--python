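patient,who_grade,impairment_grade,fugl_meyer,planar_area_mm2,deviation_index,fa,md,ad,rd
1,II,1,63,49,0.23,0.3,0.69,0.9,0.59
2,II,0,66,9,0.14,0.3,1.04,1.35,0.89
3,II,1,64,10,0.08,0.3,0.76,0.98,0.65
4,II,0,66,17,0.16,0.8,0.67,1.43,0.29
5,II,0,66,20,0.07,0.5,0.65,1.05,0.45
6,III,3,50,31,0.14,0.3,0.35,0.64,0.21
7,III,3,45,28,0.23,0.2,1.33,1.58,1.2
8,III,0,66,45,0.13,0.3,0.72,0.92,0.62
9,III,3,51,27,0.06,0.4,0.64,0.88,0.48
10,III,2,58,62,0.38,0.4,0.72,1.08,0.53
11,III,0,66,19,0.11,0.6,0.68,1.14,0.44
12,III,0,66,30,0.11,0.2,0.79,0.98,0.69
13,III,3,40,19,0.00,0.2,1.32,1.56,1.2
14,II,0,66,6,0.09,0.3,0.86,1.25,0.67
15,III,0,66,7,0.09,0.3,1.13,1.48,0.95
16,II,0,66,8,0.11,0.2,0.89,1.1,0.79
17,III,0,66,7,0.05,0.4,1.04,1.48,0.82
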