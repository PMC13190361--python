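dimension,level,decrement,se,merged_with
pain,2,-0.060,0.011,
pain,3,-0.110,0.012,
pain,4,-0.190,0.013,
pain,5,-0.270,0.015,
fatigue,2,-0.030,0.010,
fatigue,3,-0.047,0.011,
fatigue,4,-0.090,0.012,
fatigue,5,-0.130,0.013,
nausea,2,-0.070,0.011,
nausea,3,-0.120,0.012,
nausea,4,-0.190,0.013,
nausea,5,-0.255,0.015,
sleep,2,-0.030,0.010,
sleep,3,-0.060,0.011,
sleep,4,-0.100,0.012,
sleep,5,-0.140,0.013,
work,2,-0.040,0.010,
work,3,-0.075,0.011,
work,4,-0.130,0.012,
work,5,-0.185,0.014,
support,2,-0.025,0.010,
support,3,-0.050,0.011,
support,4,-0.100,0.012,
support,5,-0.150,0.013,
sadness,2,-0.035,0.010,
sadness,3,-0.070,0.011,
sadness,4,-0.120,0.012,
sadness,5,-0.175,0.014,
worry,2,-0.002,0.009,2-3
worry,3,-0.002,0.009,2-3
worry,4,-0.050,0.011,
worry,5,-0.097,0.012,
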