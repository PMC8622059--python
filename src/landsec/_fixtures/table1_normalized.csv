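year,S11,S12,S13,S14,S15,S16,S21,S22,S23,S24,S25,S26,S31,S32,S33,S34,S35
2004,0.9997,0.8999,0.7582,0.9210,1.0000,0.9996,0.7987,0.8016,0.5868,0.9836,0.1994,0.6561,1.0000,0.2109,0.7136,0.7992,0.9966
2005,0.9998,0.8973,0.7757,0.9237,0.9978,0.9996,0.8084,0.8106,0.6079,0.9863,0.2494,0.7133,1.0000,0.2427,0.7346,0.8192,1.0000
2006,1.0000,0.8950,0.7938,0.9252,0.9970,1.0000,0.8195,0.8209,0.6316,0.9918,0.2680,0.6997,1.0000,0.2827,0.7577,0.8382,0.8964
2007,0.9997,0.8948,0.7931,0.9252,0.9968,0.9980,0.8284,0.8302,0.6421,0.9945,0.3537,0.7573,1.0000,0.3462,0.7842,0.8398,0.8778
2008,0.9995,0.8946,0.7918,0.9250,0.9967,0.9961,0.8370,0.8386,0.6579,1.0000,0.5156,0.7775,1.0000,0.4071,0.8030,0.8807,0.8625
2009,0.9906,1.0000,1.0000,1.0000,0.8405,0.9409,0.8904,0.8997,0.7474,0.9452,0.5492,0.8011,1.0000,0.4422,0.8260,0.8797,0.8268
2010,0.9899,0.9991,0.9926,0.9993,0.8404,0.9393,0.9078,0.9156,0.7895,0.9507,0.7950,0.8394,1.0000,0.5204,0.8536,0.9017,0.8132
2011,0.9892,0.9989,0.9859,0.9985,0.8401,0.9385,0.9241,0.9305,0.8211,0.9589,0.7429,0.8965,1.0000,0.6132,0.8761,0.9381,0.8132
2012,0.9886,0.9983,0.9812,0.9978,0.8399,0.9370,0.9390,0.9455,0.8500,0.9644,0.8619,0.9312,1.0000,0.6735,0.8983,0.9631,0.8404
2013,0.9832,0.9934,0.9704,0.9923,0.8356,0.9311,0.9484,0.9536,0.8789,0.9589,0.9438,0.9458,1.0000,0.7379,0.9181,0.9785,0.8353
2014,0.9826,0.9927,0.9657,0.9916,0.8354,0.9307,0.9648,0.9676,0.9211,0.9753,1.0000,0.9740,1.0000,0.7940,0.9359,0.9819,0.8846
2015,0.9822,0.9922,0.9617,0.9913,0.8352,0.9287,0.9770,0.9791,0.9447,0.9781,0.9197,1.0000,1.0000,0.8451,0.9586,1.0000,0.8421
2016,0.9816,0.9916,0.9584,0.9909,0.8350,0.9268,0.9899,0.9903,0.9763,0.9836,0.9629,0.9671,1.0000,0.9067,0.9800,0.9863,0.9949
2017,0.9769,0.9915,0.7670,0.9905,0.8348,0.9240,1.0000,1.0000,1.0000,0.9863,0.9962,0.9515,1.0000,1.0000,1.0000,0.9808,0.9032
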