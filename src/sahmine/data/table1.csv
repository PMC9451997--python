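PN,PD,H,I,J,K,L,M,Class
60,1,1,0,0,1,0,1,1
61,1,1,0,1,0,1,0,0
62,1,1,1,1,0,1,1,1
63,0,0,1,1,1,1,0,0
64,1,1,0,0,1,0,1,1
65,0,0,1,0,1,0,1,0
66,1,1,1,0,1,1,0,1
67,1,1,1,1,0,1,0,1
68,1,0,1,1,1,1,0,1
69,0,1,0,0,0,1,1,0
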