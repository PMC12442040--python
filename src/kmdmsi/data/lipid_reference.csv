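name,lipid_class,formula,double_bonds,oxygens,notes
TG 50:3,TG,C53H96O6,3,6,
TG 50:2,TG,C53H98O6,2,6,
TG 50:1,TG,C53H100O6,1,6,
TG 52:4,TG,C55H98O6,4,6,
TG 52:3,TG,C55H100O6,3,6,
TG 52:2,TG,C55H102O6,2,6,
TG 54:3,TG,C57H104O6,3,6,
TG 48:2,TG,C51H94O6,2,6,
TG 48:1,TG,C51H96O6,1,6,
DG 53:9,DG,C56H92O5,9,5,
DG 53:8,DG,C56H94O5,8,5,
MG 30:0 or DG O-30:0,MG,C33H66O4,0,4,
MG 32:2 or DG O-32:2,MG,C35H66O4,2,4,
MG 32:1 or DG O-32:1,MG,C35H68O4,1,4,
MG 32:0 or DG O-32:0,MG,C35H70O4,0,4,
MG 34:2 or DG O-34:2,MG,C37H70O4,2,4,
MG 34:1 or DG O-34:1,MG,C37H72O4,1,4,
MG 34:0 or DG O-34:0,MG,C37H74O4,0,4,
PC 36:4 or PE 39:4,PC/PE,C44H80NO8P,4,8,isomers indistinguishable without MS/MS
PC 36:3 or PE 39:3,PC/PE,C44H82NO8P,3,8,
PC 36:2 or PE 39:2,PC/PE,C44H84NO8P,2,8,
PC 36:1 or PE 39:1,PC/PE,C44H86NO8P,1,8,
PC 35:1 or PE 38:1,PC/PE,C43H84NO8P,1,8,
PC 34:3 or PE 37:3,PC/PE,C42H78NO8P,3,8,
PC 34:2 or PE 37:2,PC/PE,C42H80NO8P,2,8,
PC 34:1 or PE 37:1,PC/PE,C42H82NO8P,1,8,
PC 32:1 or PE 35:1,PC/PE,C40H78NO8P,1,8,
PA 38:4,PA,C41H73O8P,4,8,
PA 38:3,PA,C41H75O8P,3,8,
PA 38:2,PA,C41H77O8P,2,8,
PA 36:3,PA,C39H71O8P,3,8,
PA 36:2,PA,C39H73O8P,2,8,
SM 36:2;O2,SM,C41H81N2O6P,2,6,
LPC O-14:0,LPC,C22H48NO6P,0,6,
LPC O-16:1,LPC,C24H50NO6P,1,6,
LPC O-16:0,LPC,C24H52NO6P,0,6,
LPC O-18:2 or LPE O-21:2,LPC,C26H52NO6P,2,6,
LPE O-19:2,LPE,C24H48NO6P,2,6,
ST 26:2;O4,ST,C26H42O4,2,4,sterol
ST 28:2;O4,ST,C28H46O4,2,4,sterol
CAR 6:0,CAR,C13H25NO4,0,4,hexanoylcarnitine
cyclo(Leu-Phe),DKP,C15H20N2O2,,2,cyclic dipeptide
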