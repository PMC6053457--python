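run,yeast_extract,malt_extract,dextrose,calcium_carbonate,starch,ammonium_carbonate,sodium_carbonate,response
1,0.1,0.25,0.1,0.05,0.25,0.0025,0.0025,1.64
2,0.1,0.25,0.1,0.05,0.25,0.0075,0.0075,1.631
3,0.1,0.25,0.3,0.15,0.75,0.0025,0.0025,1.561
4,0.1,0.75,0.1,0.15,0.75,0.0025,0.0075,1.512
5,0.1,0.75,0.3,0.05,0.75,0.0075,0.0025,1.801
6,0.1,0.75,0.3,0.15,0.25,0.0075,0.0075,1.825
7,0.3,0.25,0.3,0.15,0.25,0.0025,0.0075,2.423
8,0.3,0.25,0.3,0.05,0.75,0.0075,0.0075,2.339
9,0.3,0.25,0.1,0.15,0.75,0.0075,0.0025,2.168
10,0.3,0.75,0.3,0.05,0.25,0.0025,0.0025,2.506
11,0.3,0.75,0.1,0.15,0.25,0.0075,0.0025,2.277
12,0.3,0.75,0.1,0.05,0.75,0.0025,0.0075,2.075
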