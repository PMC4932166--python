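subject,annotated_inexperienced,avg_time_s,sd,miss_rate_pct
K.I,false,42.0,3.1,0.0
K.M,false,35.8,5.0,0.0
R.K,false,60.2,12.4,3.5
T.T,false,53.2,13.0,2.5
K.G,false,61.0,15.5,5.0
T.N,false,43.2,2.7,0.0
M.F,true,68.6,5.5,0.0
M.S,true,36.6,5.2,2.0
R.K2,true,49.4,19.8,0.0
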