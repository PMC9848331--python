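tool,N301S,S307F,V384F,T306I
Mut. Assessor,N,P,P,P
PhD-SNP,N,N,N,P
Meta-SNP,N,P,P,N
PredictSNP,N,P,N,P
PolyPhen-1,N,P,P,P
PolyPhen-2,N,P,P,P
PON-P2,N,P,N,P
PhD-SNPg,N,P,P,P
NEI Mut. Search,N,N,P,P
BayesDel_addAF,N,P,P,P
BayesDel_noAF,N,P,P,P
ClinPred,N,P,P,P
LRT,P,P,P,P
MetaRNN,N,P,P,P
MetaSVM,N,P,P,P
REVEL,N,P,P,P
CADD,N,P,N,P
Eigen-PC,N,P,N,P
Eigen,N,P,N,P
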