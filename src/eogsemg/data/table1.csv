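subject,pattern,correct,reject,trials
K.G,right,8,1,9
K.G,left,9,0,9
K.G,right_blink,9,0,9
K.G,left_blink,9,0,9
K.G,bite,4,5,9
T.N,right,9,0,9
T.N,left,9,0,9
T.N,right_blink,9,0,9
T.N,left_blink,7,0,9
T.N,bite,8,1,9
M.Y,right,9,0,9
M.Y,left,8,0,9
M.Y,right_blink,9,0,9
M.Y,left_blink,8,0,9
M.Y,bite,4,5,9
K.N,right,9,0,9
K.N,left,9,0,9
K.N,right_blink,9,0,9
K.N,left_blink,9,0,9
K.N,bite,8,1,9
M.F,right,9,0,9
M.F,left,9,0,9
M.F,right_blink,9,0,9
M.F,left_blink,9,0,9
M.F,bite,3,6,9
R.K,right,8,0,9
R.K,left,9,0,9
R.K,right_blink,7,0,9
R.K,left_blink,7,0,9
R.K,bite,9,0,9
K.M,right,7,2,9
K.M,left,8,1,9
K.M,right_blink,8,0,9
K.M,left_blink,9,0,9
K.M,bite,5,4,9
T.T,right,9,0,9
T.T,left,9,0,9
T.T,right_blink,9,0,9
T.T,left_blink,9,0,9
T.T,bite,7,2,9
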