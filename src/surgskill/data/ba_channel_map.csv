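ba,channel
1,C4
1,CCP4h
2,C3
2,CP3
2,CCP3h
2,CPP3h
5,Cz
5,CP1
5,CP2
5,C1
5,C2
5,CCP1h
5,CCP2h
5,CPP1h
5,CPP2h
6,FC1
6,FC2
6,FCz
6,FC4
6,FCC3h
6,FCC4h
6,FCC2h
6,FCC1h
7,Pz
7,P1
7,P2
8,F4
8,F3
8,Fz
8,F1
8,F2
8,AFF1
8,AFF2
8,FFC3
8,FFC4
8,FFC1
8,FFC2
9,AF3
9,AFz
10,AFp3h
10,AFp4h
10,FPz
10,FP3
10,FP4
10,FP1
10,FP2
18,O1
18,O2
18,I1
18,I2
18,OI1h
18,OI2h
18,POO9h
18,POO10h
19,PPO2
19,PPO1
19,POO3h
19,POO4h
19,PO3
19,PO4
19,PO7
19,PO8
20,FT9
20,FT10
20,PO9
20,P9
20,FTT9h
20,FTT10h
20,PPO9h
21,TP7
21,TP8
21,TPP10h
21,TTP8h
21,TPP7h
21,TPP8h
21,T8
21,TPP9h
37,PO10
37,P10
37,PPO10h
37,P7
37,P8
39,P3
39,P4
39,P5
39,P6
39,PPO5h
39,PPO6h
40,CP5
40,CP6
40,CP4
40,CPP5h
40,CPP6h
41,C6
41,CCP6h
42,CCP5h
42,TTP7h
42,T7
42,C5
44,FC6
44,FC5
44,FCC6h
45,FFT8h
45,FFT7h
46,AFF5h
46,AFF6h
46,AF7
46,F5
46,FFC5h
46,FFC6h
46,FCC5h
47,FTT7h
47,FTT8h
47,F7
47,FT7
47,FT8
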