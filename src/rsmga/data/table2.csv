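yeast_extract,dextrose,starch,ammonium_carbonate,observed,predicted,residual
0.4,0.4,0.8,0.02,1.694,1.698545,-0.004545
0.4,0.4,0.8,0.02,1.7,1.698545,0.001455
0.6,0.6,0.4,0.01,2.168,2.164430,0.003570
0,0.4,0.8,0.02,0.66,0.788276,-0.128276
0.2,0.2,0.4,0.01,0.76,0.749693,0.010307
0.4,0.4,1.6,0.02,1.96,2.097274,-0.137274
0.4,0.4,0.8,0,1.25,1.326244,-0.076244
0.8,0.4,0.8,0.02,2.788,2.823809,-0.035809
0.2,0.2,1.2,0.01,1.534,1.394519,0.139481
0.4,0.4,0.8,0.02,1.7,1.698545,0.001455
0.4,0,0.8,0.02,1.33,1.402118,-0.072118
0.4,0.4,0.8,0.04,1.8,1.854525,-0.054525
0.6,0.2,1.2,0.03,2.427,2.344019,0.082981
0.6,0.2,0.4,0.03,2.023,2.019173,0.003827
0.4,0.8,0.8,0.02,1.926,1.977144,-0.051144
0.4,0.4,0.8,0.02,1.69,1.698545,-0.008545
0.4,0.4,0.8,0.02,1.7,1.698545,0.001455
0.4,0.4,0,0.02,1.35,1.283244,0.066756
0.4,0.4,0.8,0.02,1.71,1.698545,0.011455
0.4,0.4,0.8,0.02,1.7,1.698545,0.001455
0.4,0.4,0.8,0.02,1.69,1.698545,-0.008545
0.2,0.6,1.2,0.03,1.855,1.743433,0.111567
0.2,0.6,0.4,0.03,1.2,1.193526,0.006474
0.6,0.6,1.2,0.01,1.939,1.832878,0.106122
0.4,0.4,0.8,0.02,1.71,1.698545,0.011455
0.4,0.4,0.8,0.02,1.7,1.698545,0.001455
0.4,0.4,0.8,0.02,1.69,1.698545,-0.008545
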