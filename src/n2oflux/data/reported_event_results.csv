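treatment,site,event,n_in_kg_ha,background_kg_ha,linear_cumulative_kg_ha,linear_minus_background_kg_ha,bayes_cumulative_kg_ha,bayes_ci_low_kg_ha,bayes_ci_high_kg_ha,bayes_minus_background_kg_ha,linear_ef_pct,bayes_ef_pct
AN,EB,1,70,0.25,1.66,1.41,1.59,1.02,2.86,1.34,2.02,1.92
AN,EB,2,70,0.19,0.31,0.11,0.45,0.32,0.68,0.25,0.16,0.36
AN,HF,1,90,0.01,0.06,0.04,0.05,0.05,0.06,0.04,0.05,0.04
AN,HF,2,90,0.04,0.14,0.10,0.15,0.13,0.16,0.10,0.11,0.12
AN,HF,3,60,0.06,0.18,0.11,0.19,0.17,0.21,0.13,0.19,0.21
AN,NW,1,90,0.23,0.88,0.65,1.65,0.96,3.50,1.43,0.73,1.59
AN,NW,2,90,0.16,0.41,0.25,0.70,0.38,1.61,0.54,0.28,0.61
AN,NW,3,60,0.07,0.10,0.03,0.20,0.14,0.34,0.14,0.06,0.23
AN,UJ,1,70,0.92,1.50,0.59,1.39,0.97,2.26,0.48,0.84,0.68
AN,UJ,2,70,0.51,0.43,-0.08,0.50,0.39,0.67,-0.01,-0.11,-0.01
AN,UJ,3,70,0.93,1.66,0.73,1.53,1.08,2.34,0.60,1.05,0.85
Ur,EB,1,70,0.25,0.51,0.26,0.52,0.37,0.78,0.27,0.37,0.38
Ur,EB,2,70,0.19,0.23,0.03,0.30,0.24,0.40,0.11,0.05,0.15
Ur,HF,1,90,0.01,0.06,0.05,0.06,0.05,0.07,0.05,0.05,0.05
Ur,HF,2,90,0.04,0.28,0.24,0.25,0.22,0.28,0.21,0.26,0.23
Ur,HF,3,60,0.06,0.33,0.27,0.32,0.29,0.35,0.26,0.45,0.43
Ur,NW,1,90,0.23,0.32,0.09,0.63,0.36,1.43,0.40,0.10,0.45
Ur,NW,2,90,0.16,0.25,0.09,0.53,0.30,1.13,0.37,0.10,0.41
Ur,NW,3,60,0.07,0.11,0.04,0.18,0.11,0.37,0.12,0.07,0.19
Ur,UJ,1,70,0.92,0.89,-0.03,0.99,0.72,1.48,0.07,-0.04,0.10
Ur,UJ,2,70,0.51,0.81,0.31,1.06,0.64,2.10,0.55,0.44,0.79
Ur,UJ,3,70,0.93,1.08,0.15,0.97,0.77,1.27,0.04,0.22,0.05
UI,EB,1,70,0.25,0.48,0.23,0.54,0.37,0.90,0.28,0.33,0.41
UI,EB,2,70,0.19,0.23,0.04,0.29,0.23,0.40,0.10,0.06,0.14
UI,HF,1,90,0.01,0.07,0.06,0.07,0.06,0.07,0.05,0.07,0.06
UI,HF,2,90,0.04,0.19,0.15,0.18,0.16,0.19,0.14,0.17,0.15
UI,HF,3,60,0.06,0.31,0.25,0.28,0.25,0.32,0.22,0.41,0.37
UI,NW,1,90,0.23,0.10,-0.13,0.26,0.15,0.51,0.03,-0.14,0.03
UI,NW,2,90,0.16,0.25,0.10,0.43,0.26,0.89,0.27,0.11,0.30
UI,NW,3,60,0.07,0.07,0.01,0.16,0.09,0.33,0.09,0.01,0.15
UI,UJ,1,70,0.92,1.13,0.22,1.33,0.87,2.46,0.41,0.31,0.58
UI,UJ,2,70,0.51,0.49,-0.02,0.67,0.50,0.97,0.17,-0.03,0.24
UI,UJ,3,70,0.93,1.26,0.33,1.22,0.89,1.83,0.29,0.46,0.41
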