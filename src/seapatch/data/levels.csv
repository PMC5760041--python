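level,mean_density,area_m2,abundance,c_i_kg
1,0.425,802792,341187,433106
2,0.375,7073065,2652400,3815919
3,0.325,15031861,4885355,8109689
4,0.275,30024581,8256760,16198261
5,0.225,46682137,10503481,25185013
6,0.175,55090317,9640805,29721226
7,0.125,62916404,7864551,33943400
8,0.068,111522754,7583547,60166526
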