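sample,donor,condition,ACTB,B2M,GAPDH,HPRT1,RPLP0
ASC1 F,ASC1,F,17.96,19.15,19.73,25.90,18.25
ASC2 F,ASC2,F,18.71,19.78,20.71,26.44,18.54
ASC3 F,ASC3,F,18.77,19.71,20.55,26.51,18.66
ASC1 F+IL1,ASC1,F+IL1,19.03,19.66,21.02,26.34,19.06
ASC2 F+IL1,ASC2,F+IL1,18.88,20.24,21.17,26.68,19.50
ASC3 F+IL1,ASC3,F+IL1,19.54,20.38,21.29,26.59,19.59
ASC1 S,ASC1,S,21.09,20.42,22.20,28.01,19.36
ASC2 S,ASC2,S,20.50,20.07,21.77,27.44,19.06
ASC3 S,ASC3,S,21.50,20.68,22.18,28.30,19.38
ASC1 S+IL1,ASC1,S+IL1,20.78,20.43,22.33,27.39,19.86
ASC2 S+IL1,ASC2,S+IL1,20.34,19.64,21.96,27.12,19.48
ASC3 S+IL1,ASC3,S+IL1,20.69,20.18,22.59,28.02,19.98
ASC1 F+IL1/S,ASC1,F+IL1/S,19.90,19.28,20.38,26.71,18.43
ASC2 F+IL1/S,ASC2,F+IL1/S,20.30,19.58,21.04,27.20,18.90
ASC3 F+IL1/S,ASC3,F+IL1/S,21.05,20.33,22.13,28.07,19.88
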