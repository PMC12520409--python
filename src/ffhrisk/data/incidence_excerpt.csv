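ID,A1,A2,A3,B1,B2,B3,B4,B5,B6,B7,B8,C1,C2,C3,D1,D2,D3,E1,E2,E3
001,1,0,1,1,1,0,0,0,0,1,0,0,0,1,1,0,0,0,1,0
002,0,0,1,1,1,0,0,1,0,1,0,0,0,1,0,0,0,0,0,0
003,1,0,0,0,1,0,1,0,1,1,0,0,0,0,1,0,1,1,0,0
004,1,1,0,1,1,0,0,0,0,1,0,0,0,0,1,0,1,1,0,0
005,0,0,1,0,1,0,1,0,0,0,0,0,0,0,1,0,0,1,1,0
006,0,0,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0
007,1,1,1,0,0,1,0,0,0,1,0,0,0,0,1,0,1,1,0,0
008,0,0,1,0,1,0,1,0,0,0,0,0,0,0,1,0,1,0,0,0
009,1,1,0,0,1,1,0,0,0,0,0,0,0,0,1,0,1,1,0,0
010,1,1,0,0,1,1,0,0,0,0,0,1,0,1,0,0,1,1,1,1
011,1,1,0,0,1,0,0,0,1,0,0,1,0,1,1,0,0,0,0,0
364,0,0,1,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0
365,0,0,0,1,0,0,1,1,0,0,0,0,0,0,0,0,0,1,1,0
366,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0,1,0,1,0
367,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,0,1,1,0
368,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0
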