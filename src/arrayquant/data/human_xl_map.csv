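well,analyte,dup_group,control
A1,Reference Spot,CTRL-POS,pos
A3,Adiponectin,G001,
A4,Adiponectin,G001,
A5,Aggrecan,G002,
A6,Aggrecan,G002,
A7,Angiogenin,G003,
A8,Angiogenin,G003,
A9,Angiopoietin-1,G004,
A10,Angiopoietin-1,G004,
A11,Angiopoietin-2,G005,
A12,Angiopoietin-2,G005,
A13,BAFF,G006,
A14,BAFF,G006,
A15,BDNF,G007,
A16,BDNF,G007,
A17,CD14,G008,
A18,CD14,G008,
A19,CD30,G009,
A20,CD30,G009,
A21,CD40 ligand,G010,
A22,CD40 ligand,G010,
A24,Reference Spot,CTRL-POS,pos
B1,Chitinase 3-like 1,G011,
B2,Chitinase 3-like 1,G011,
B3,Complement C5/C5a,G012,
B4,Complement C5/C5a,G012,
B7,Complement Factor D,G013,
B8,Complement Factor D,G013,
B9,C-Reactive Protein,G014,
B10,C-Reactive Protein,G014,
B11,Cripto-1,G015,
B12,Cripto-1,G015,
B13,Cystatin C,G016,
B14,Cystatin C,G016,
B15,Dkk-1,G017,
B16,Dkk-1,G017,
B17,DPPIV,G018,
B18,DPPIV,G018,
B19,EGF,G019,
B20,EGF,G019,
B21,EMMPRIN,G020,
B22,EMMPRIN,G020,
B23,ENA-78,G021,
B24,ENA-78,G021,
C1,Endoglin,G022,
C2,Endoglin,G022,
C5,Fas Ligand,G023,
C6,Fas Ligand,G023,
C7,FGF basic,G024,
C8,FGF basic,G024,
C9,FGF-7,G025,
C10,FGF-7,G025,
C11,FGF-19,G026,
C12,FGF-19,G026,
C13,Flt-3 Ligand,G027,
C14,Flt-3 Ligand,G027,
C15,G-CSF,G028,
C16,G-CSF,G028,
C17,GDF-15,G029,
C18,GDF-15,G029,
C19,GM-CSF,G030,
C20,GM-CSF,G030,
C21,GROα,G031,
C22,GROα,G031,
C23,Growth Hormone,G032,
C24,Growth Hormone,G032,
D3,HGF,G033,
D4,HGF,G033,
D5,ICAM-1,G034,
D6,ICAM-1,G034,
D7,IFN-γ,G035,
D8,IFN-γ,G035,
D9,IGFBP-2,G036,
D10,IGFBP-2,G036,
D11,IGFBP-3,G037,
D12,IGFBP-3,G037,
D13,IL-1α,G038,
D14,IL-1α,G038,
D15,IL-1β,G039,
D16,IL-1β,G039,
D17,IL-1ra,G040,
D18,IL-1ra,G040,
D19,IL-2,G041,
D20,IL-2,G041,
D21,IL-3,G042,
D22,IL-3,G042,
D23,IL-4,G043,
D24,IL-4,G043,
E3,IL-5,G044,
E4,IL-5,G044,
E5,IL-6,G045,
E6,IL-6,G045,
E7,IL-8,G046,
E8,IL-8,G046,
E9,IL-10,G047,
E10,IL-10,G047,
E11,IL-11,G048,
E12,IL-11,G048,
E13,IL-12 p70,G049,
E14,IL-12 p70,G049,
E15,IL-13,G050,
E16,IL-13,G050,
E17,IL-15,G051,
E18,IL-15,G051,
E19,IL-16,G052,
E20,IL-16,G052,
E21,IL-17A,G053,
E22,IL-17A,G053,
F3,IL-18 BPa,G054,
F4,IL-18 BPa,G054,
F5,IL-19,G055,
F6,IL-19,G055,
F7,IL-22,G056,
F8,IL-22,G056,
F9,IL-23,G057,
F10,IL-23,G057,
F11,IL-24,G058,
F12,IL-24,G058,
F13,IL-27,G059,
F14,IL-27,G059,
F15,IL-31,G060,
F16,IL-31,G060,
F17,IL-32,G061,
F18,IL-32,G061,
F19,IL-33,G062,
F20,IL-33,G062,
F21,IL-34,G063,
F22,IL-34,G063,
G1,IP-10,G064,
G2,IP-10,G064,
G3,I-TAC,G065,
G4,I-TAC,G065,
G5,Kallikrein 3,G066,
G6,Kallikrein 3,G066,
G7,Leptin,G067,
G8,Leptin,G067,
G9,LIF,G068,
G10,LIF,G068,
G11,Lipocalin-2,G069,
G12,Lipocalin-2,G069,
G13,MCP-1,G070,
G14,MCP-1,G070,
G15,MCP-3,G071,
G16,MCP-3,G071,
G17,M-CSF,G072,
G18,M-CSF,G072,
G19,MIF,G073,
G20,MIF,G073,
G23,MIG,G074,
G24,MIG,G074,
H1,MIP-1α/MIP-1β,G075,
H2,MIP-1α/MIP-1β,G075,
H3,MIP-3α,G076,
H4,MIP-3α,G076,
H5,MIP-3β,G077,
H6,MIP-3β,G077,
H7,MMP-9,G078,
H8,MMP-9,G078,
H9,Myeloperoxidase,G079,
H10,Myeloperoxidase,G079,
H11,Osteopontin,G080,
H12,Osteopontin,G080,
H13,PDGF-AA,G081,
H14,PDGF-AA,G081,
H15,PDGF-AB/BB,G082,
H16,PDGF-AB/BB,G082,
H17,Pentraxin 3,G083,
H18,Pentraxin 3,G083,
H19,PF4,G084,
H20,PF4,G084,
H23,RAGE,G085,
H24,RAGE,G085,
I1,RANTES,G086,
I2,RANTES,G086,
I3,RBP-4,G087,
I4,RBP-4,G087,
I5,Relaxin-2,G088,
I6,Relaxin-2,G088,
I7,Resistin,G089,
I8,Resistin,G089,
I9,SDF-1α,G090,
I10,SDF-1α,G090,
I11,Serpin E1,G091,
I12,Serpin E1,G091,
I13,SHBG,G092,
I14,SHBG,G092,
I15,ST2,G093,
I16,ST2,G093,
I17,TARC,G094,
I18,TARC,G094,
I19,TFF3,G095,
I20,TFF3,G095,
I23,TfR,G096,
I24,TfR,G096,
J1,Reference Spot,CTRL-POS,pos
J3,TGF-α,G097,
J4,TGF-α,G097,
J5,Thrombospondin-1,G098,
J6,Thrombospondin-1,G098,
J7,TNF-α,G099,
J8,TNF-α,G099,
J9,uPAR,G100,
J10,uPAR,G100,
J11,VEGF,G101,
J12,VEGF,G101,
J13,Vitamin D BP,G102,
J14,Vitamin D BP,G102,
J15,CD31,G103,
J16,CD31,G103,
J17,TIM-3,G104,
J18,TIM-3,G104,
J19,VCAM-1,G105,
J20,VCAM-1,G105,
J24,Negative Control,CTRL-NEG,neg
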