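experiment,time_min,coded_A,mass_mg,coded_B,retention_pct
1,10,-1,34.2,-1.00024,89.28
2,90,1,34.3,-0.99726,100
3,10,-1,100.9,0.98742,100
4,90,1,101.3,0.99934,100
5,50,0,65.1,-0.07942,100
6,50,0,60.1,-0.22842,100
7,50,0,65.6,-0.06452,100
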