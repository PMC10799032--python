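label,x,y,z
C4,0.84088868,0.07467407,0.53603173
CCP4h,0.66967044,-0.14252871,0.72885325
C3,-0.83544982,0.06539130,0.54566251
CP3,-0.76721788,-0.36081072,0.53027572
CCP3h,-0.66438128,-0.15003115,0.73218042
CPP3h,-0.55021158,-0.55365793,0.62508408
Cz,-0.00349176,0.09615679,0.99536008
CP1,-0.42795188,-0.36055438,0.82876880
CP2,0.44548399,-0.35766473,0.82074354
C1,-0.47167701,0.08728364,0.87744080
C2,0.48024508,0.09316087,0.87217299
CCP1h,-0.23747915,-0.14376247,0.96069558
CCP2h,0.24368070,-0.14150250,0.95947733
CPP1h,-0.18994049,-0.56181571,0.80516192
CPP2h,0.21222956,-0.55254602,0.80600962
FC1,-0.43114919,0.53132265,0.72925073
FC2,0.42805757,0.54267517,0.72268276
FCz,-0.00374544,0.54806724,0.83642589
FC4,0.75716285,0.49797388,0.42276049
FCC3h,-0.66364522,0.30761515,0.68187091
FCC4h,0.66327267,0.31861492,0.67716607
FCC2h,0.23469805,0.33759553,0.91156244
FCC1h,-0.24172380,0.33123178,0.91206092
Pz,-0.00397474,-0.72336993,0.69044923
P1,-0.33051700,-0.71888001,0.61153090
P2,0.34689305,-0.70714904,0.61612129
F4,0.56994749,0.79217616,0.21821270
F3,-0.57218546,0.78556395,0.23556969
Fz,-0.00416480,0.85724845,0.51488615
F1,-0.31982647,0.83699071,0.44402430
F2,0.32577284,0.84055209,0.43283281
AFF1,-0.25878854,0.92504894,0.27805206
AFF2,0.26287907,0.92298845,0.28104610
FFC3,-0.67177114,0.65870318,0.33887116
FFC4,0.66972372,0.66767418,0.32508666
FFC1,-0.37531761,0.70930639,0.59667507
FFC2,0.38026317,0.71255528,0.58963115
AF3,-0.34465265,0.93873029,-0.00000374
AFz,-0.00453142,0.98958000,0.14391277
AFp3h,-0.17216040,0.97914297,-0.10788805
AFp4h,0.17464663,0.98016670,-0.09365790
FPz,-0.00526199,0.97696166,-0.21335001
FP3,-0.31349941,0.94053584,-0.13080693
FP4,0.31004319,0.94222275,-0.12684445
FP1,-0.27667708,0.92533344,-0.25924470
FP2,0.26655266,0.92852054,-0.25845558
O1,-0.29783889,-0.94670850,-0.12261736
O2,0.29023077,-0.94893180,-0.12367108
I1,-0.26712834,-0.85639455,-0.44184932
I2,0.25597295,-0.85836237,-0.44462556
OI1h,-0.14626021,-0.95305920,-0.26511528
OI2h,0.13594524,-0.95446496,-0.26554760
POO9h,-0.40764510,-0.85453389,-0.32186534
POO10h,0.40168748,-0.85815445,-0.31971566
PPO2,0.28577361,-0.83756049,0.46564564
PPO1,-0.28299850,-0.84354609,0.45644478
POO3h,-0.21669898,-0.97207939,0.09001787
POO4h,0.20758337,-0.97480277,0.08166209
PO3,-0.39866849,-0.90103626,0.17087157
PO4,0.38936475,-0.90643824,0.16359956
PO7,-0.55688338,-0.80974462,-0.18491772
PO8,0.55269660,-0.81237948,-0.18591949
FT9,-0.73486038,0.27197400,-0.62129733
FT10,0.72945037,0.27246832,-0.62742583
PO9,-0.48933916,-0.71518515,-0.49905649
P9,-0.65784780,-0.50856046,-0.55552006
FTT9h,-0.84725358,0.14939996,-0.50974604
FTT10h,0.84399367,0.15163587,-0.51447182
PPO9h,-0.62520387,-0.67864882,-0.38542950
TP7,-0.90306902,-0.30861155,-0.29870597
TP8,0.90301035,-0.30584096,-0.30171778
TPP10h,0.77849272,-0.43943033,-0.44816300
TTP8h,0.98201413,-0.14985292,-0.11485792
TPP7h,-0.86528477,-0.49250841,-0.09336885
TPP8h,0.86854051,-0.48683502,-0.09289267
T8,0.93951661,0.01981518,-0.34192967
TPP9h,-0.78148709,-0.43571818,-0.44657317
PO10,0.48040168,-0.71906724,-0.50215190
P10,0.65286302,-0.51352166,-0.55683515
PPO10h,0.61920512,-0.68340309,-0.38671079
P7,-0.76569964,-0.59331450,-0.24835854
P8,0.76422376,-0.59412386,-0.25095595
P3,-0.60288232,-0.69611309,0.38981979
P4,0.61149490,-0.68679318,0.39292380
P5,-0.75004181,-0.65665859,0.07897334
P6,0.74873976,-0.65843916,0.07646333
PPO5h,-0.58994121,-0.78853581,0.17372577
PPO6h,0.58620130,-0.79173564,0.17182175
CP5,-0.93168209,-0.34530606,0.11283708
CP6,0.93647048,-0.33202073,0.11307200
CP4,0.77678574,-0.35151668,0.52253224
CPP5h,-0.79214877,-0.53169299,0.29967131
CPP6h,0.80042215,-0.52086986,0.29667992
C6,0.99422138,0.04833240,0.09585311
CCP6h,0.93021326,-0.14471849,0.33728303
CCP5h,-0.92848535,-0.15574444,0.33713295
TTP7h,-0.98088510,-0.15727583,-0.11458067
T7,-0.94074153,0.00866794,-0.33901362
C5,-0.99453927,0.03735384,0.09744917
FC6,0.90584536,0.42199993,0.03688155
FC5,-0.90955134,0.41387379,0.03774717
FCC6h,0.91901522,0.26654055,0.29046025
FFT8h,0.82738529,0.53232926,-0.17905068
FFT7h,-0.82849842,0.53009339,-0.18053078
AFF5h,-0.53702100,0.84334529,0.01942062
AFF6h,0.53399796,0.84531730,0.01687746
AF7,-0.52035871,0.80018272,-0.29821876
F5,-0.70800465,0.70465515,-0.04680304
FFC5h,-0.76622119,0.61874035,0.17339397
FFC6h,0.76249917,0.62652530,0.16143439
FCC5h,-0.92039081,0.25771038,0.29405121
FTT7h,-0.96751929,0.20539011,-0.14738154
FTT8h,0.96486908,0.21737239,-0.14756998
F7,-0.72358766,0.60459323,-0.33299839
FT7,-0.87639621,0.33269194,-0.34820361
FT8,0.87082452,0.34577864,-0.34943067
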