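grader,cv_percent,icc,sensitivity,specificity,kappa
AD3RI,28.8,0.92,0.68,0.96,0.58
THRESH,41.1,0.67,0.74,0.94,0.49
OP1,28.3,0.86,0.58,0.98,0.55
OP2,23.6,0.79,0.66,0.98,0.61
OP3,15.0,0.92,0.69,0.97,0.64
OP4,19.6,0.92,0.61,0.96,0.53
TE1,16.3,0.92,0.66,0.98,0.64
TE2,14.2,0.89,0.65,0.98,0.62
TE3,21.9,0.90,0.76,0.96,0.64
TE4,41.2,0.82,0.77,0.93,0.57
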