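human,chimpanzee,mouse,rat
MMP1,MMP1,Mmp1a,Mmp1
MMP2,MMP2,Mmp2,Mmp2
MMP3,MMP3,Mmp3,Mmp3
MMP7,MMP7,Mmp7,Mmp7
MMP9,MMP9,Mmp9,Mmp9
MMP12,MMP12,Mmp12,Mmp12
MMP13,MMP13,Mmp13,Mmp13
MMP14,MMP14,Mmp14,Mmp14
PLAU,PLAU,Plau,Plau
PLAT,PLAT,Plat,Plat
F2,F2,F2,F2
PRTN3,PRTN3,Prtn3,Prtn3
ELANE,ELANE,Elane,Elane
CTSB,CTSB,Ctsb,Ctsb
CTSL,CTSL,Ctsl,Ctsl
CTSD,CTSD,Ctsd,Ctsd
GZMA,GZMA,Gzma,Gzma
GZMB,GZMB,Gzmb,Gzmb
GZMH,GZMH,,
KLK3,,,
CASP3,CASP3,Casp3,Casp3
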