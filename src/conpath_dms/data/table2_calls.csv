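tool,K303N,N373S,D375N,D375H,E399K,T390I,V407A,T400S,W402S
Mut. Assesor,P,N,N,N,N,P,P,N,P
PhD-SNP,P,N,N,P,P,N,N,N,P
Meta-SNP,N,N,N,N,N,N,N,N,P
PredictSNP,N,N,N,N,N,P,N,N,N
PolyPhen-1,N,N,N,P,N,P,N,N,N
PolyPhen-2,P,N,N,N,N,P,N,N,N
PON-P2,P,N,N,N,N,P,P,N,N
PhD-SNPg,N,N,P,P,P,P,P,P,P
NEI Mut. Search,N,N,N,N,N,P,P,N,P
BayesDel_addAF,P,N,N,N,N,P,P,P,P
BayesDel_noAF,P,N,N,N,P,P,P,P,P
ClinPred,P,N,P,P,N,P,P,P,P
LRT,P,N,N,P,P,P,P,P,P
MetaRNN,P,N,N,N,N,P,P,N,P
MetaSVM,P,N,N,N,P,P,P,N,P
REVEL,P,N,N,N,P,P,P,P,P
CADD,P,N,P,P,P,P,P,N,P
Eigen-PC,N,N,N,N,P,P,P,N,P
Eigen,P,N,N,N,P,P,P,N,P
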