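gene,parameter,category,weight
HLA-A,HLA-A,MHC,1
HLA-B,HLA-B,MHC,1
HLA-C,HLA-C,MHC,1
HLA-DPA1,HLA-DPA1,MHC,1
HLA-DPB1,HLA-DPB1,MHC,1
HLA-E,HLA-E,MHC,1
HLA-F,HLA-F,MHC,1
TAP1,TAP1,MHC,1
TAP2,TAP2,MHC,1
B2M,B2M,MHC,1
PDCD1,PDCD1,CP,-1
CTLA4,CTLA4,CP,-1
CD274,CD274,CP,-1
PDCD1LG2,PDCD1LG2,CP,-1
LAG3,LAG3,CP,-1
HAVCR2,HAVCR2,CP,-1
TIGIT,TIGIT,CP,-1
IDO1,IDO1,CP,-1
BTLA,BTLA,CP,-1
VSIR,VSIR,CP,-1
CD8A,Act_CD8,EC,1
GZMB,Act_CD8,EC,1
IFNG,Act_CD8,EC,1
CD69,Act_CD4,EC,1
ICOS,Act_CD4,EC,1
IL2,Act_CD4,EC,1
EOMES,Tem_CD8,EC,1
KLRG1,Tem_CD8,EC,1
CXCR3,Tem_CD8,EC,1
IL7R,Tem_CD4,EC,1
CCR5,Tem_CD4,EC,1
CD40LG,Tem_CD4,EC,1
FOXP3,Treg,SC,-1
IL2RA,Treg,SC,-1
CCR8,Treg,SC,-1
ARG1,MDSC,SC,-1
ITGAM,MDSC,SC,-1
CD14,MDSC,SC,-1
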