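participant,group,eeg_valence,eeg_arousal,user_valence,user_arousal
01,photographic,-0.86,0.34,2,6
02,photographic,-0.91,0.64,1,9
03,photographic,-0.76,0.47,2,7
04,photographic,-0.85,0.55,3,7
05,photographic,-0.73,0.49,3,7
06,photographic,-0.93,0.51,1,7
07,photographic,-0.81,0.58,2,7
08,photographic,-0.84,0.63,1,8
09,photographic,-0.85,0.65,1,8
10,photographic,-0.86,0.61,1,9
11,photographic,-0.84,0.59,3,8
12,photographic,-0.88,0.52,1,7
13,photographic,-0.92,0.51,1,7
14,photographic,-0.78,0.48,2,5
15,photographic,-0.83,0.53,1,7
16,photographic,-0.89,0.55,1,7
17,photographic,-0.79,0.59,1,7
18,photographic,-0.80,0.53,2,7
19,photographic,-0.76,0.51,4,6
20,photographic,-0.74,0.55,2,7
21,illustrated,-0.68,0.21,2,3
22,illustrated,-0.39,0.24,4,5
23,illustrated,-0.54,0.09,1,4
24,illustrated,-0.48,0.19,4,5
25,illustrated,-0.45,0.17,4,4
26,illustrated,-0.53,0.18,3,5
27,illustrated,-0.59,0.13,2,5
28,illustrated,-0.52,0.25,3,6
29,illustrated,-0.63,0.21,2,5
30,illustrated,-0.61,0.311,3,6
31,illustrated,-0.43,0.26,3,6
32,illustrated,-0.47,0.24,5,6
33,illustrated,-0.51,0.23,3,5
34,illustrated,-0.56,0.28,3,5
35,illustrated,-0.64,0.27,3,6
36,illustrated,-0.65,0.26,1,7
37,illustrated,-0.59,0.23,3,5
38,illustrated,-0.58,0.26,3,6
39,illustrated,-0.52,0.31,2,6
40,illustrated,-0.61,0.33,3,6
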