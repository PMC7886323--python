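protein_change,position,ref,alt,n_populations
,63,A,T,1
,84,A,G,1
,87,T,C,1
,91,T,C,1
,124,T,C,1
,175,C,T,1
,193,T,C,1
,217,T,A,1
D106G,316,A,G,13
,353,T,C,1
,383,C,T,1
,412,A,G,1
,417,T,C,1
,422,T,A,1
,428,A,G,1
,475,A,G,1
,487,A,G,1
,500,T,C,1
,518,A,G,1
,527,T,G,1
,611,T,C,1
,621,T,C,1
,662,G,A,1
,681,A,G,1
,698,T,C,1
,722,T,C,1
,734,A,G,1
,741,T,C,1
,745,T,C,1
D253N,756,G,A,14
,780,C,T,1
,785,T,A,1
,796,A,G,1
,814,T,C,1
I292M,875,A,G,15
,878,G,A,1
,924,A,G,1
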