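analyte,symbol
Adiponectin,ADIPOQ
Aggrecan,ACAN
Angiogenin,ANG
Angiopoietin-1,ANGPT1
Angiopoietin-2,ANGPT2
BAFF,TNFSF13B
BDNF,BDNF
CD14,CD14
CD30,TNFRSF8
CD40 ligand,CD40LG
Chitinase 3-like 1,CHI3L1
Complement C5/C5a,C5
Complement Factor D,CFD
C-Reactive Protein,CRP
Cripto-1,TDGF1
Cystatin C,CST3
Dkk-1,DKK1
DPPIV,DPP4
EGF,EGF
EMMPRIN,BSG
ENA-78,CXCL5
Endoglin,ENG
Fas Ligand,FASLG
FGF basic,FGF2
FGF-7,FGF7
FGF-19,FGF19
Flt-3 Ligand,FLT3LG
G-CSF,CSF3
GDF-15,GDF15
GM-CSF,CSF2
GROα,CXCL1
Growth Hormone,GH1
HGF,HGF
ICAM-1,ICAM1
IFN-γ,IFNG
IGFBP-2,IGFBP2
IGFBP-3,IGFBP3
IL-1α,IL1A
IL-1β,IL1B
IL-1ra,IL1RN
IL-2,IL2
IL-3,IL3
IL-4,IL4
IL-5,IL5
IL-6,IL6
IL-8,CXCL8
IL-10,IL10
IL-11,IL11
IL-12 p70,IL12A
IL-13,IL13
IL-15,IL15
IL-16,IL16
IL-17A,IL17A
IL-18 BPa,IL18BP
IL-19,IL19
IL-22,IL22
IL-23,IL23A
IL-24,IL24
IL-27,IL27
IL-31,IL31
IL-32,IL32
IL-33,IL33
IL-34,IL34
IP-10,CXCL10
I-TAC,CXCL11
Kallikrein 3,KLK3
Leptin,LEP
LIF,LIF
Lipocalin-2,LCN2
MCP-1,CCL2
MCP-3,CCL7
M-CSF,CSF1
MIF,MIF
MIG,CXCL9
MIP-1α/MIP-1β,CCL3
MIP-3α,CCL20
MIP-3β,CCL19
MMP-9,MMP9
Myeloperoxidase,MPO
Osteopontin,SPP1
PDGF-AA,PDGFA
PDGF-AB/BB,PDGFB
Pentraxin 3,PTX3
PF4,PF4
RAGE,AGER
RANTES,CCL5
RBP-4,RBP4
Relaxin-2,RLN2
Resistin,RETN
SDF-1α,CXCL12
Serpin E1,SERPINE1
SHBG,SHBG
ST2,IL1RL1
TARC,CCL17
TFF3,TFF3
TfR,TFRC
TGF-α,TGFA
Thrombospondin-1,THBS1
TNF-α,TNF
uPAR,PLAUR
VEGF,VEGFA
Vitamin D BP,GC
CD31,PECAM1
TIM-3,HAVCR2
VCAM-1,VCAM1
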