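system,donor_chain,donor_resid,donor_name,acceptor_chain,acceptor_resid,acceptor_name,class,occupancy
WT,A,303,LYS,A,401,ILE,direct,0.99
WT,A,303,LYS,A,398,ASP,direct,0.55
WT,A,373,ASN,A,322,GLY,water_mediated,0.30
WT,A,375,ASP,A,378,ASP,direct,0.90
WT,A,375,ASP,A,377,ALA,direct,0.55
WT,A,399,GLU,A,396,CYS,direct,0.60
WT,A,399,GLU,A,376,LYS,direct,0.70
WT,A,390,THR,B,332,LYS,direct,0.80
WT,A,390,THR,A,406,GLU,direct,0.99
WT,A,400,THR,A,396,CYS,direct,0.80
WT,A,400,THR,A,398,ASP,direct,0.80
WT,A,402,TRP,A,404,GLU,direct,0.70
WT,A,402,TRP,A,394,ILE,direct,0.75
WT,A,301,ASN,A,299,TYR,water_mediated,0.30
WT,A,307,SER,B,404,GLU,direct,0.90
WT,A,306,THR,A,403,LEU,direct,1.00
WT,A,306,THR,A,368,TYR,direct,0.55
WT,A,306,THR,A,307,SER,direct,0.55
WT,A,306,THR,A,287,VAL,direct,0.90
K303N,A,303,ASN,A,401,ILE,direct,0.99
N373S,A,373,SER,A,322,GLY,water_mediated,0.28
D375N,A,375,ASN,A,378,ASP,direct,0.87
D375N,A,375,ASN,A,377,ALA,direct,0.52
D375H,A,375,HIS,A,378,ASP,direct,0.88
D375H,A,375,HIS,A,377,ALA,direct,0.80
E399K,A,399,LYS,A,396,CYS,direct,0.60
T390I,A,390,ILE,B,332,LYS,direct,0.45
T390I,A,390,ILE,A,406,GLU,direct,0.75
T400S,A,400,SER,A,396,CYS,direct,0.80
T400S,A,400,SER,A,398,ASP,direct,0.80
W402S,A,402,SER,A,394,ILE,direct,0.75
W402S,A,402,SER,A,404,GLU,direct,0.45
N301S,A,301,SER,A,299,TYR,water_mediated,0.28
S307F,A,306,THR,A,307,PHE,direct,0.55
T306I,A,306,ILE,A,287,VAL,direct,0.60
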