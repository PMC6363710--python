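{"LG":{"exchangeabilities_lower_triangle":[0.425093,0.276818,0.395144,2.489084,0.969894,1.038545,2.06604,0.358858,0.14983,0.395337,0.536518,1.124035,0.253701,1.177651,4.727182,2.139501,0.180717,0.218959,2.54787,0.751878,0.123954,0.534551,2.807908,0.36397,0.390192,2.426601,0.126991,0.301848,6.326067,0.484133,0.052722,0.332533,0.858151,0.578987,0.593607,0.31444,0.170887,5.076149,0.528768,1.695752,0.541712,1.437645,4.509238,0.191503,0.068427,2.145078,0.371004,0.089525,0.161787,4.008358,2.000679,0.045376,0.612025,0.083688,0.062556,0.523386,5.24387,0.844926,0.927114,0.01069,0.015076,0.282959,0.025548,0.017416,0.394456,1.240275,0.42586,0.02989,0.135107,0.037967,0.084808,0.003499,0.569265,0.640543,0.320627,0.594007,0.013266,0.89368,1.105251,0.075382,2.784478,1.14348,0.670128,1.165532,1.959291,4.128591,0.267959,4.813505,0.072854,0.582457,3.234294,1.672569,0.035855,0.624294,1.223828,1.080136,0.236199,0.257336,0.210332,0.348847,0.423881,0.044265,0.069673,1.807177,0.173735,0.018811,0.419409,0.611973,0.604545,0.077852,0.120037,0.245034,0.311484,0.008705,0.044261,0.296636,0.139538,0.089586,0.196961,1.73999,0.129836,0.268491,0.054679,0.076701,0.108882,0.366317,0.697264,0.442472,0.682139,0.508851,0.990012,0.584262,0.597054,5.306834,0.119013,4.145067,0.159069,4.273607,1.112727,0.078281,0.064105,1.033739,0.11166,0.232523,10.649107,0.1375,6.312358,2.592692,0.24906,0.182287,0.302936,0.619632,0.299648,1.702745,0.656604,0.023918,0.390322,0.748683,1.136863,0.049906,0.131932,0.185202,1.798853,0.099849,0.34696,2.020366,0.696175,0.481306,1.898718,0.094464,0.361819,0.165001,2.457121,7.803902,0.654683,1.338132,0.571468,0.095131,0.089613,0.296501,6.472279,0.248862,0.400547,0.098369,0.140825,0.245841,2.188158,3.151815,0.18951,0.249313],"frequencies":[0.0790659209340791,0.0559409440590559,0.041976958023042,0.0530519469480531,0.0129369870630129,0.0407669592330408,0.0715859284140716,0.0573369426630573,0.0223549776450224,0.0621569378430622,0.0990809009190991,0.0645999354000646,0.022950977049023,0.0423019576980423,0.044039955960044,0.0611969388030612,0.0532869467130533,0.0120659879340121,0.0341549658450342,0.0691469308530692]},"WAG":{"exchangeabilities_lower_triangle":[0.551571,0.509848,0.738998,1.02704,0.908598,1.58285,1.41672,0.316954,0.193335,0.397915,0.906265,0.893496,0.210494,1.43855,3.37079,2.12111,0.113133,0.240735,2.00601,0.635346,0.147304,0.528191,3.0355,0.439157,0.584665,2.13715,0.186979,0.497671,5.35142,0.683162,0.102711,0.679489,1.22419,0.554413,1.16392,0.381533,0.251849,5.42942,0.265256,1.54364,0.947198,1.12556,3.95629,0.554236,0.131528,3.01201,0.198221,0.0961621,0.195081,3.97423,2.03006,0.0719167,1.086,0.196246,0.0302949,0.616783,6.17416,0.865584,0.930676,0.039437,0.0848047,0.479855,0.103754,0.0467304,0.423984,1.07176,0.374866,0.129767,0.325711,0.152335,0.0988179,0.021352,0.306674,0.248972,0.170135,0.384287,0.0740339,0.390482,0.39802,0.109404,1.40766,0.512984,0.71707,0.543833,1.00214,5.46947,0.330052,4.29411,0.113917,0.869489,3.8949,1.54526,0.0999208,0.933372,1.02887,0.857928,0.215737,0.22771,0.301281,0.567717,0.570025,0.127395,0.154263,2.58443,0.315124,0.0811339,0.682355,0.704939,0.822765,0.156557,0.196303,0.588731,0.24941,0.0304501,0.0613037,0.373558,0.1741,0.049931,0.24357,1.34182,0.225833,0.336983,0.103604,0.187247,0.13819,0.499462,0.890432,0.404141,0.679371,0.696198,0.740169,0.473307,0.262569,3.87344,0.118358,3.17097,0.323832,4.25746,1.05947,0.0999288,0.31944,1.45816,0.212483,0.42017,7.8213,0.257555,4.85402,2.11517,0.415844,0.344739,0.326622,0.665309,0.398618,1.80034,0.934276,0.088836,0.556896,0.96713,1.38698,0.137505,0.133264,0.305434,1.19063,0.171329,0.493905,1.51612,0.515706,0.428437,2.05845,0.161444,0.545931,0.171903,1.52964,6.45428,0.649892,1.61328,0.795384,0.139405,0.216046,0.314887,4.37802,0.523742,0.786993,0.232739,0.110864,0.291148,1.38823,2.48539,0.365369,0.31473],"frequencies":[0.0866279086627909,0.0439720043972004,0.0390894039089404,0.0570451057045106,0.0193078019307802,0.0367281036728104,0.0580589058058906,0.0832518083251808,0.0244313024431302,0.0484660048466005,0.0862090086209009,0.0620286062028606,0.0195027019502702,0.0384319038431904,0.0457631045763105,0.0695179069517907,0.0610127061012706,0.0143859014385901,0.0352742035274204,0.0708956070895607]},"JTT":{"exchangeabilities_lower_triangle":[58,54,81,56,57,105,179,27,36,30,35,54,15,194,378,475,9,11,298,45,16,113,310,29,137,328,22,38,646,44,5,74,101,64,126,20,17,528,34,86,58,81,391,47,12,263,30,10,15,503,232,8,70,16,10,49,767,130,112,11,7,26,15,4,15,59,38,4,46,31,9,5,59,69,17,23,7,31,78,14,223,42,115,209,62,323,26,597,9,72,292,43,4,164,53,51,18,24,20,119,26,12,9,181,18,5,18,30,32,10,7,45,23,6,6,27,14,5,24,201,33,55,8,47,16,56,45,33,40,115,73,46,8,573,11,229,21,479,89,10,40,245,9,32,961,14,388,248,102,59,25,52,24,180,65,4,21,47,103,10,8,14,43,16,29,226,24,18,323,17,92,12,53,536,62,285,118,6,10,23,477,35,63,38,12,21,112,71,25,16],"frequencies":[0.0767479232520768,0.0516909483090517,0.0426449573550427,0.0515439484560515,0.0198029801970198,0.0407519592480408,0.0618299381700618,0.0731519268480732,0.0229439770560229,0.0537609462390538,0.0919039080960919,0.0586759413240587,0.0238259761740238,0.0401259598740401,0.0509009490990509,0.0687649312350688,0.0585649414350586,0.0142609857390143,0.0321019678980321,0.066004933995066]},"amino_acid_order":["A","R","N","D","C","Q","E","G","H","I","L","K","M","F","P","S","T","W","Y","V"]}
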