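study_id,vessel_class,gene
Keuschnigg,BEC,NRCAM
Keuschnigg,BEC,CXCL1
Keuschnigg,BEC,TAGLN
Keuschnigg,BEC,RNASE1
Keuschnigg,BEC,CAP2
Keuschnigg,BEC,PLA2G4A
Keuschnigg,BEC,ISG15
Keuschnigg,BEC,DKK1
Keuschnigg,BEC,IFI27
Keuschnigg,BEC,FSTL1
Keuschnigg,BEC,MCAM
Keuschnigg,BEC,ZNF207
Keuschnigg,BEC,VAMP8
Keuschnigg,BEC,RGS5
Keuschnigg,BEC,SEC61B
Keuschnigg,BEC,GLIPR1
Keuschnigg,BEC,SH3BP4
Keuschnigg,BEC,EMP3
Keuschnigg,BEC,TSPAN3
Keuschnigg,BEC,HOXB2
Keuschnigg,BEC,JAM3
Keuschnigg,BEC,NCL
Keuschnigg,BEC,RP3-523C21.1
Keuschnigg,BEC,CCT5
Keuschnigg,BEC,SHISA3
Keuschnigg,BEC,MCTP1
Keuschnigg,BEC,GATA6
Keuschnigg,BEC,C1ORF54
Petrova,BEC,NRCAM
Petrova,BEC,CXCL1
Petrova,BEC,TAGLN
Petrova,BEC,RNASE1
Petrova,BEC,CAP2
Petrova,BEC,PLA2G4A
Petrova,BEC,ISG15
Petrova,BEC,DKK1
Petrova,BEC,IFI27
Petrova,BEC,CD44
Petrova,BEC,LTBP2
Petrova,BEC,ITGA5
Petrova,BEC,BMP6
Petrova,BEC,VCAN
Petrova,BEC,CXCR4
Petrova,BEC,SRGN
Petrova,BEC,IL4R
Petrova,BEC,FLT1
Petrova,BEC,PCDH1
Petrova,BEC,VEGFC
Petrova,BEC,CDH2
Petrova,BEC,COL1A2
Petrova,BEC,PGF
Petrova,BEC,CCL2
Petrova,BEC,C17ORF72
Petrova,BEC,ICAM2
Petrova,BEC,ITGB5
Petrova,BEC,CCRL2
Petrova,BEC,COL6A1
Petrova,BEC,IL8
Petrova,BEC,AXL
Petrova,BEC,FAP
Petrova,BEC,ACTA2
Petrova,BEC,KRT7
Petrova,BEC,LPHN2
Petrova,BEC,SELP
Petrova,BEC,TPM2
Petrova,BEC,SERPINE1
Petrova,BEC,IGF2BP3
Petrova,BEC,PLAU
Petrova,BEC,PFN2
Petrova,BEC,CHST1
Petrova,BEC,MMP1
Petrova,BEC,BASP1
Petrova,BEC,MLLT11
Petrova,BEC,CLU
Petrova,BEC,TGFBI
Petrova,BEC,IL6
Petrova,BEC,TRIM22
Hirakawa,BEC,NRCAM
Hirakawa,BEC,CXCL1
Hirakawa,BEC,CD44
Hirakawa,BEC,LTBP2
Hirakawa,BEC,ITGA5
Hirakawa,BEC,BMP6
Hirakawa,BEC,VCAN
Hirakawa,BEC,CXCR4
Hirakawa,BEC,SRGN
Hirakawa,BEC,IL4R
Hirakawa,BEC,FLT1
Hirakawa,BEC,PCDH1
Hirakawa,BEC,VEGFC
Hirakawa,BEC,CDH2
Hirakawa,BEC,COL1A2
Hirakawa,BEC,PGF
Hirakawa,BEC,CCL2
Hirakawa,BEC,C17ORF72
Hirakawa,BEC,ICAM2
Hirakawa,BEC,ITGB5
Hirakawa,BEC,CCRL2
Hirakawa,BEC,COL6A1
Hirakawa,BEC,AUTS2
Hirakawa,BEC,DSG1
Hirakawa,BEC,ITGA4
Hirakawa,BEC,GPR39
Hirakawa,BEC,COL6A3
Hirakawa,BEC,IL13RA2
Hirakawa,BEC,FBLN5
Hirakawa,BEC,BMP1
Hirakawa,BEC,CSF2RB
Hirakawa,BEC,ITGB3
Hirakawa,BEC,VWF
Hirakawa,BEC,F2R
Hirakawa,BEC,ESM1
Hirakawa,BEC,EFEMP2
Hirakawa,BEC,CD93
Hirakawa,BEC,SPARC
Hirakawa,BEC,LAMC1
Hirakawa,BEC,LAMB2
Hirakawa,BEC,PECAM1
Hirakawa,BEC,FN1
Hirakawa,BEC,LAMB1
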