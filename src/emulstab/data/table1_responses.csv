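run,combination,creaming_class,size_t0_um,size_t5_um,delta_printed_um,size_var_printed_pct
1,m/m/m/M/m,2,15.87,28.56,12.69,79.96
2,a/a/a/a/a,2,29.34,42.17,12.83,43.72
3,M/m/M/m/M,1,58.32,67.04,8.72,14.95
4,M/m/m/m/m,1,55.62,115.4,59.78,107.48
5,M/m/M/M/m,2,20.52,24.8,4.28,20.86
6,M/M/m/M/m,2,12.58,20.62,8.04,63.91
7,m/M/M/m/m,1,56.22,66.65,10.43,18.55
8,m/M/m/M/M,3,11.41,12.49,1.08,9.46
9,a/a/a/a/a,2,23.6,31.96,8.36,35.42
10,m/M/M/M/m,4,10.9,11.67,0.77,7.06
11,M/m/m/M/M,3,14.01,15.63,1.62,11.56
12,m/m/M/m/m,1,64.82,77.82,13,20.05
13,m/M/m/m/m,1,48.14,65.65,17.51,36.37
14,m/M/M/m/M,2,20.71,25.25,4.54,21.92
15,M/M/M/m/m,1,21.8,30.34,8.54,39.17
16,a/a/a/a/a,2,26.45,33.17,6.72,25.40
17,M/M/m/m/M,2,24.77,31.06,6.29,25.39
18,m/m/M/M/M,3,12.66,13.79,1.13,8.92
19,m/M/m/M/m,1,22.23,43.39,21.16,95.18
20,M/M/m/m/m,1,31.24,45.66,14.42,46.16
21,M/m/m/M/m,2,12.81,35.82,23.01,179.62
22,M/m/M/m/m,1,59.69,108.19,48.5,81.25
23,m/m/m/m/M,1,15.16,35.7,20.54,135.49
24,M/M/M/M/M,5,11.24,11.27,0.03,0.27
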