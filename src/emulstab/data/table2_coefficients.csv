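term,size_t0,size_t5,var_rate
transform,log10,sqrt,sqrt
r2_raw,0.96,0.96,0.93
r2_adjusted,0.93,0.93,0.88
r2_predicted,0.85,0.8,0.74
const,1.34,5.81,5.72
A,0.0087,0.027,-0.29
B,-0.065,-0.73,-0.96
C,0.026,-0.15,-1.6
D,-0.21,-1.62,-0.96
E,-0.072,-0.89,-1.51
AB,-0.055,-0.55,
AE,0.079,0.33,-0.9
BC,-0.067,0.68,
BD,,0.41,
DE,,-0.66,
CE,0.031,0.31,
DE2,0.047,,-0.94
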