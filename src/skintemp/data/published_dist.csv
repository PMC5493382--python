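n_sensors,subset_id,n_samples,mse,mae,cve,q1,q3,mae_day,mae_night,LF,RF,LH,RH
1,LF,,1.318,0.830,0.848,-0.607,0.561,,,1.018,0,0,0
1,RF,,0.983,0.706,0.710,-0.434,0.519,,,0,1.017,0,0
1,LH,,1.322,0.805,0.813,-0.504,0.557,,,0,0,0.980,0
1,RH,,1.075,0.762,0.777,-0.522,0.582,,,0,0,0,0.982
2,LF+RF,,0.960,0.691,0.707,-0.437,0.483,,,0.205,0.812,0,0
2,LF+LH,,0.107,0.241,0.248,-0.186,0.166,,,0.510,0,0.490,0
2,LF+RH,,0.094,0.223,0.233,-0.158,0.164,,,0.481,0,0,0.519
2,RF+LH,,0.085,0.215,0.225,-0.155,0.168,,,0,0.550,0.451,0
2,RF+RH,,0.106,0.239,0.246,-0.154,0.193,,,0,0.522,0,0.479
2,LH+RH,,0.925,0.689,0.709,-0.406,0.536,,,0,0,0.373,0.608
3,LF+RF+LH,,0.057,0.172,0.181,-0.116,0.122,,,0.226,0.323,0.453,0
3,LF+RF+RH,,0.066,0.180,0.186,-0.107,0.129,,,0.270,0.246,0,0.484
3,LF+LH+RH,,0.028,0.119,0.128,-0.086,0.089,,,0.464,0,0.248,0.286
3,RF+LH+RH,,0.034,0.131,0.139,-0.097,0.100,,,0,0.504,0.260,0.236
4,LF+RF+LH+RH,,0,0,0,0,0,,,0.25,0.25,0.25,0.25
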