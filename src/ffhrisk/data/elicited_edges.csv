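from,to,expert_support,frontline_support,bel,pl,k
B4,B2,0.88,0.790,0.9650,0.9650,0.2796
B2,B1,0.84,0.807,0.9564,0.9564,0.2912
B2,C3,0.84,0.754,0.9415,0.9415,0.3273
B2,B7,0.91,0.832,0.9804,0.9804,0.2278
B1,D1,0.81,0.795,0.9430,0.9430,0.3171
B1,C3,0.68,0.771,0.8774,0.8774,0.4024
B7,C3,0.77,0.812,0.9353,0.9353,0.3315
B7,D3,0.77,0.802,0.9313,0.9313,0.3369
B7,D2,0.73,0.768,0.8995,0.8995,0.3767
D3,C3,0.77,0.756,0.9121,0.9121,0.3618
D2,E2,0.67,0.727,0.8439,0.8439,0.4228
B6,C1,0.65,0.761,0.8554,0.8554,0.4217
B3,A1,0.85,0.778,0.9521,0.9521,0.3054
A1,A3,0.88,0.761,0.9589,0.9589,0.3016
B8,B5,0.76,0.737,0.8987,0.8987,0.3768
B5,E1,0.79,0.705,0.8999,0.8999,0.3811
A3,E1,0.90,0.761,0.9663,0.9663,0.2912
C2,E1,0.77,0.717,0.8945,0.8945,0.3828
D1,FFHA,0.84,0.798,0.9540,0.9540,0.2974
C1,FFHA,0.88,0.761,0.9589,0.9589,0.3016
C3,FFHA,0.82,0.751,0.9322,0.9322,0.3394
E2,FFHA,0.84,0.766,0.9450,0.9450,0.3191
E1,FFHA,0.81,0.793,0.9423,0.9423,0.3183
E3,FFHA,0.77,0.744,0.9068,0.9068,0.3682
A2,FFHA,0.84,0.785,0.9504,0.9504,0.3062
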