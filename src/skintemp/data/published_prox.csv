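n_sensors,subset_id,n_samples,mse,mae,cve,q1,q3,mae_day,mae_night,A,LIA,RIA,LMT,RMT
1,A,,0.688,0.677,0.714,-0.557,0.610,,,0.981,0,0,0,0
1,LIA,,1.332,0.936,0.968,-0.745,0.862,,,0,0.971,0,0,0
1,RIA,,1.229,0.893,0.916,-0.686,0.809,,,0,0,0.971,0,0
1,LMT,,1.909,1.091,1.127,-0.904,0.894,,,0,0,0,1.036,0
1,RMT,,2.005,1.106,1.144,-0.941,0.762,,,0,0,0,0,1.039
2,A+LIA,,0.590,0.621,0.662,-0.436,0.558,,,0.720,0.259,0,0,0
2,A+RIA,,0.563,0.604,0.641,-0.434,0.553,,,0.685,0,0.293,0,0
2,A+LMT,,0.148,0.300,0.307,-0.226,0.257,,,0.632,0,0,0.370,0
2,A+RMT,,0.131,0.285,0.296,-0.218,0.250,,,0.635,0,0,0,0.367
2,LIA+RIA,,1.165,0.864,0.899,-0.647,0.789,,,0,0.372,0.599,0,0
2,LIA+LMT,,0.162,0.319,0.330,-0.265,0.268,,,0,0.535,0,0.467,0
2,LIA+RMT,,0.184,0.330,0.353,-0.256,0.264,,,0,0.542,0,0,0.461
2,RIA+LMT,,0.169,0.324,0.343,-0.269,0.275,,,0,0,0.546,0.455,0
2,RIA+RMT,,0.195,0.341,0.367,-0.252,0.283,,,0,0,0.554,0,0.448
2,LMT+RMT,,1.767,1.046,1.099,-0.882,0.772,,,0,0,0,0.585,0.453
3,A+LIA+RIA,,0.562,0.604,0.655,-0.430,0.555,,,0.678,0.045,0.255,0,0
3,A+LIA+LMT,,0.035,0.136,0.146,-0.099,0.101,,,0.347,0.277,0,0.375,0
3,A+LIA+RMT,,0.032,0.138,0.144,-0.121,0.102,,,0.372,0.260,0,0,0.367
3,A+RIA+LMT,,0.033,0.142,0.151,-0.101,0.122,,,0.351,0,0.281,0.366,0
3,A+RIA+RMT,,0.032,0.133,0.136,-0.097,0.107,,,0.379,0,0.262,0,0.359
3,A+LMT+RMT,,0.114,0.263,0.279,-0.204,0.230,,,0.619,0,0,0.162,0.223
3,LIA+RIA+LMT,,0.131,0.287,0.301,-0.233,0.233,,,0,0.285,0.266,0.450,0
3,LIA+RIA+RMT,,0.154,0.304,0.325,-0.232,0.245,,,0,0.297,0.261,0,0.443
3,LIA+LMT+RMT,,0.134,0.286,0.313,-0.222,0.234,,,0,0.524,0,0.274,0.206
3,RIA+LMT+RMT,,0.144,0.298,0.328,-0.242,0.254,,,0,0,0.535,0.276,0.192
4,A+LIA+RIA+LMT,,0.025,0.121,0.133,-0.096,0.105,,,0.325,0.144,0.160,0.370,0
4,A+LIA+RIA+RMT,,0.024,0.115,0.119,-0.094,0.087,,,0.353,0.141,0.143,0,0.363
4,A+LIA+LMT+RMT,,0.009,0.067,0.074,-0.054,0.049,,,0.344,0.269,0,0.190,0.198
4,A+RIA+LMT+RMT,,0.009,0.070,0.076,-0.042,0.058,,,0.351,0,0.270,0.189,0.190
4,LIA+RIA+LMT+RMT,,0.106,0.254,0.280,-0.203,0.212,,,0,0.287,0.252,0.268,0.194
5,A+LIA+RIA+LMT+RMT,,0,0,0,0,0,,,0.324,0.1465,0.1465,0.1915,0.1915
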