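# n = 283
,ADS,PACS,COUNT,DRINC,CIWA,STEPS,RECOG,AMBIV,BAI,BDI,DPDD,BINGE_PCT
mean,40.25,17.92,5.23,40.9,5.66,2.8,2.72,3.09,18.82,20.56,7.08,0.66
sd,7.31,6.61,2.81,22.12,6.92,0.93,0.92,0.92,12.99,12.04,4.66,0.3
ADS,1,0.5,0.48,0.65,0.23,0.24,0.48,0.44,0.29,0.23,0.26,0.33
PACS,0.5,1,0.35,0.52,0.27,0.16,0.48,0.44,0.29,0.32,0.26,0.22
COUNT,0.48,0.35,1,0.54,0.3,0.28,0.51,0.46,0.04,0.06,0.22,0.36
DRINC,0.65,0.52,0.54,1,0.23,0.35,0.68,0.58,0.28,0.27,0.2,0.33
CIWA,0.23,0.27,0.3,0.23,1,0.09,0.21,0.15,0.05,0.07,0.22,0.25
STEPS,0.24,0.16,0.28,0.35,0.09,1,0.57,0.61,0.07,0.1,0.05,0.11
RECOG,0.48,0.48,0.51,0.68,0.21,0.57,1,0.8,0.23,0.24,0.2,0.31
AMBIV,0.44,0.44,0.46,0.58,0.15,0.61,0.8,1,0.13,0.17,0.17,0.28
BAI,0.29,0.29,0.04,0.28,0.05,0.07,0.23,0.13,1,0.83,0.03,0.02
BDI,0.23,0.32,0.06,0.27,0.07,0.1,0.24,0.17,0.83,1,0.002,-0.004
DPDD,0.26,0.26,0.22,0.2,0.22,0.05,0.2,0.17,0.03,0.002,1,0.62
BINGE_PCT,0.33,0.22,0.36,0.33,0.25,0.11,0.31,0.28,0.02,-0.004,0.62,1
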