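feature,overall_shap,pcc_label,accuracy_pct
D-Mean,0.639,0.695,77.98
D-Variance,1.335,0.614,78.53
D-Skewness,0.420,0.802,71.73
D-Kurtosis,0.068,0.697,69.49
D-Median,0.115,0.701,75.40
IH-Mean,0.582,0.670,78.53
IHR-Mean,0.474,0.663,77.56
IH-Median,0.563,0.723,77.40
IHC-Variation,0.059,0.832,70.75
D-Entropy,0.383,0.772,75.08
D-Uniformity,0.010,0.795,69.17
D-Ten,0.226,0.613,70.94
D-Ninety,0.314,0.682,77.56
IH-Mode,0.365,0.735,77.40
D-Minimum,0.000,0.000,63.37
D-Maximum,0.018,0.436,69.65
D-Interquartile,0.037,0.648,74.87
D-Range,0.018,0.436,69.65
IHC-Dispersion,0.030,0.714,69.49
G-Maximum,0.154,0.588,70.19
GI-Maximum,0.160,0.649,70.78
G-Minimum,0.164,0.660,69.73
GI-Minimum,0.164,0.818,72.86
I-Mean,1.391,0.692,78.11
I-Median,0.129,0.704,76.77
I-STD,1.675,0.647,78.30
I-Maximum,0.023,0.355,65.88
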