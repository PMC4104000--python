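record,multiplicity,position,wt,mut,note
S01,single,473,G,S,
S02,single,476,V,A,
S03,single,488,E,G,
S04,single,525,K,E,
S05,single,535,S,P,
S06,single,538,R,G,
S07,single,542,E,G,
S08,single,543,L,P,
S09,single,545,H,Y,
S10,single,557,D,E,
S11,single,559,D,V,
S12,single,559,D,G,
S13,single,564,V,A,
S14,single,567,K,R,
D01,double,474,S,P,
D01,double,508,E,K,
D02,double,489,F,L,
D02,double,535,S,P,
D03,double,560,N,D,
D03,double,568,R,G,
T01,triple,473,G,C,
T01,triple,488,E,D,
T01,triple,543,L,P,
F01,frameshift,,,,IDIHRGK-L
F02,frameshift,,,,IFTEVNSSGK-V
F03,frameshift,,,,NSSSGRIVTDR574Stop
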