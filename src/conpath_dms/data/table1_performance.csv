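tool,TP,TN,FP,FN,recall,precision,specificity,accuracy
Mut. Assessor,24,2,1,3,0.89,0.96,0.67,0.87
Meta-SNP,23,2,1,4,0.85,0.96,0.67,0.83
PredictSNP,21,2,1,6,0.78,0.95,0.67,0.77
PolyPhen-1,21,2,1,6,0.78,0.95,0.67,0.77
PolyPhen-2,23,2,1,4,0.85,0.96,0.67,0.83
PhD-SNP,23,2,1,4,0.85,0.96,0.67,0.83
PON-P2,24,2,1,3,0.89,0.96,0.67,0.87
PhD-SNPg,27,2,1,0,1.00,0.96,0.67,0.97
NEI Mut. Search,22,2,1,5,0.81,0.96,0.67,0.80
BayesDel_addAF,27,2,1,0,1.00,0.96,0.67,0.97
BayesDel_noAF,27,2,1,0,1.00,0.96,0.67,0.97
ClinPred,24,3,0,3,0.89,1.00,1.00,0.90
LRT,26,2,1,1,0.96,0.96,0.67,0.93
MetaRNN,27,3,0,0,1.00,1.00,1.00,1.00
MetaSVM,26,2,1,1,0.96,0.96,0.67,0.93
REVEL,27,2,1,0,1.00,0.96,0.67,0.97
CADD,27,2,1,0,1.00,0.96,0.67,0.97
Eigen-PC,27,2,1,0,1.00,0.96,0.67,0.97
Eigen,26,2,1,1,0.96,0.96,0.67,0.93
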