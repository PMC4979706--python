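site,n,diversity,included,D-19,O-26,N-7,G-38,A-273,E-9,F-9,F-12,F-14,K-36
SFB South,44,0.428,1,-,1,9,1,-,-,-,32,1,-
SFB East,54,0.205,1,-,-,48,2,-,-,1,3,-,-
SFB West,17,0.208,1,-,-,2,-,-,-,-,15,-,-
SFB-unk,10,-,0,-,-,2,4,-,-,-,4,-,-
Half Moon Bay,24,0.517,1,-,7,2,15,-,-,-,-,-,-
Monterey,115,0.235,1,-,1,4,100,-,-,-,10,-,-
Morro Bay,19,0.100,1,-,-,1,18,-,-,-,-,-,-
Santa Barbara,13,0.000,1,-,-,-,-,-,-,-,-,-,13
SJV North,33,0.691,1,-,-,5,14,-,-,-,10,4,-
SJV South,28,0.513,1,-,-,7,3,-,18,-,-,-,-
Southern CA,9,0.593,1,-,-,-,-,2,-,5,2,-,-
Contact zone,9,0.593,1,5,-,1,3,-,-,-,-,2,-
North coastal,5,-,0,-,-,-,5,-,-,-,-,-,-
Presidio,4,-,0,-,3,-,1,-,-,-,-,-,-
Miscellaneous,6,-,0,-,-,-,4,-,-,1,1,-,-
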