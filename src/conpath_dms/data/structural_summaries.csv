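system,second_half_mean_rmsd,rmsf_baseline,rmsf_peak_max
WT,1.00,0.6,
K303N,1.05,0.7,
N373S,1.05,0.7,
D375N,1.05,0.7,
D375H,1.05,0.7,
E399K,1.05,0.7,
T390I,1.05,0.7,
V407A,1.05,0.7,
T400S,1.05,0.7,
W402S,1.05,0.7,
N301S,1.60,0.7,2.9
S307F,1.60,0.7,2.9
V384F,1.60,0.7,2.9
T306I,1.60,0.7,2.9
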