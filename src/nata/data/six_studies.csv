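study_id,NoP,DoM,factor,count
S1,201,10,NoTab,5
S1,201,10,SidEff,3
S1,201,10,NoMed,4
S1,201,10,Other,13
S2,33,5,SidEff,1
S2,33,5,ClinImp,1
S2,33,5,Other,4
S3,331,6,SidEff,9
S3,331,6,Forgot,21
S3,331,6,Other,7
S4,313,7,SidEff,20
S4,313,7,NoSym,42
S4,313,7,Other,16
S5,326,5,SidEff,24
S5,326,5,Forgot,7
S5,326,5,NoSym,13
S5,326,5,Other,4
S6,246,10,SidEff,24
S6,246,10,NoMed,1
S6,246,10,Forgot,22
S6,246,10,Other,9
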