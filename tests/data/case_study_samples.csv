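dose_gy,time,n_cells,focus_count,scorer
0,1h,200,68,S1
0,1h,200,143,S1
0,1h,200,69,S1
0,24h,200,117,S1
0,24h,200,64,S1
0,24h,200,16,S2
0.75,1h,53,293,S1
0.75,24h,200,153,S1
1.5,1h,200,1004,S1
1.5,24h,200,583,S1
3,1h,200,1305,S1
3,24h,200,552,S2
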