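run,block,space_type,oil_pct,starch_pct,caseinate_pct,stir_rpm,stir_min
1,1,vertex,10,0,0,20000,5
2,1,center,15,0.75,1,15000,12.5
3,1,vertex,20,0,2,10000,20
4,1,vertex,20,0,0,10000,5
5,1,vertex,20,0,2,20000,5
6,1,vertex,20,1.5,0,20000,5
7,1,vertex,10,1.5,2,10000,5
8,1,vertex,10,1.5,0,20000,20
9,2,center,15,0.75,1,15000,12.5
10,2,vertex,10,1.5,2,20000,5
11,2,vertex,20,0,0,20000,20
12,2,vertex,10,0,2,10000,5
13,2,vertex,10,1.5,0,10000,5
14,2,vertex,10,1.5,2,10000,20
15,2,vertex,20,1.5,2,10000,5
16,2,center,15,0.75,1,15000,12.5
17,3,vertex,20,1.5,0,10000,20
18,3,vertex,10,0,2,20000,20
19,3,vertex,10,1.5,0,20000,5
20,3,vertex,20,1.5,0,10000,5
21,3,vertex,20,0,0,20000,5
22,3,vertex,20,0,2,10000,5
23,3,vertex,10,0,0,10000,20
24,3,vertex,20,1.5,2,20000,20
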