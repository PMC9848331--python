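variant,structural,interaction,conpath,conpath_votes,class
K303N,-,+,+,13,MHPPV
N373S,-,-,-,0,LPPV
D375N,-,-,-,3,LPPV
D375H,-,-,-,6,LPPV
E399K,-,+,-,9,MLPPV
T390I,-,+,+,17,MHPPV
V407A,-,-,+,14,MLPPV
T400S,-,-,-,6,LPPV
W402S,-,+,+,15,MHPPV
N301S,+,-,-,1,MLPPV
S307F,+,+,+,17,HPPV
V384F,+,-,+,13,MHPPV
T306I,+,+,+,18,HPPV
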