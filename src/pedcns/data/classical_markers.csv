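cell_type,gene
AST,GFAP
AST,AQP4
EN,FN1
EN,COL4A1
MAC/MG,CSF1R
MAC/MG,PTPRC
NEU/UBC,RBFOX3
NEU/UBC,RELN
NEU_INH/INT,GAD2
NSC,SOX2
NSC,CD44
OLIG,MOG
OLIG,PLP1
OPC,PDGFRA
RGC,VIM
RGC,NES
RGC,PAX6
ST,FAP
TC,CD3E
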