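year,comprehensive_value,S1,S2,S3,level
2004,0.2973,0.1038,0.0947,0.0988,U
2005,0.2997,0.1040,0.0958,0.0999,U
2006,0.3024,0.1041,0.0971,0.1012,U
2007,0.3047,0.1041,0.0982,0.1024,U
2008,0.3066,0.1040,0.0992,0.1034,U
2009,0.3255,0.1091,0.1055,0.1109,U
2010,0.3295,0.1090,0.1076,0.1129,U
2011,0.3330,0.1088,0.1095,0.1147,U
2012,0.3366,0.1087,0.1113,0.1166,U
2013,0.3381,0.1081,0.1124,0.1176,U
2014,0.3416,0.1080,0.1143,0.1193,U
2015,0.3444,0.1079,0.1158,0.1207,U
2016,0.3472,0.1078,0.1173,0.1221,U
2017,0.3472,0.1054,0.1185,0.1233,U
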