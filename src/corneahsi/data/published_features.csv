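eye_id,label,mean,std,skewness,kurtosis
1,healthy,135.31,28.10,0.69,4.79
2,healthy,97.23,28.67,0.92,5.86
3,healthy,101.50,27.87,0.84,6.09
4,healthy,80.91,22.34,1.22,8.73
5,healthy,88.11,25.90,0.95,7.26
6,healthy,102.41,26.99,1.04,6.47
7,healthy,100.73,19.88,1.10,7.74
8,healthy,108.48,21.03,1.25,9.66
9,healthy,89.85,24.00,1.26,8.21
10,healthy,99.75,27.72,0.89,6.08
11,healthy,98.96,22.73,1.18,8.66
12,injured,125.85,26.46,0.51,5.36
13,injured,110.69,26.74,0.83,6.45
14,injured,81.23,22.58,1.43,8.40
15,injured,82.07,23.08,0.83,5.81
16,injured,76.56,19.28,1.16,8.80
17,injured,79.44,28.30,1.02,5.54
18,injured,67.84,20.04,1.11,8.01
19,injured,73.76,27.27,1.11,6.24
20,injured,116.46,27.40,0.61,4.64
21,injured,120.36,21.74,0.76,6.61
22,injured,96.72,27.15,0.94,6.51
23,injured,108.97,28.55,0.67,5.71
24,injured,101.93,29.25,0.27,4.67
25,injured,105.74,24.04,0.37,4.67
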