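study_id,vessel_class,gene
Keuschnigg,LEC,PROX1
Keuschnigg,LEC,PDPN
Keuschnigg,LEC,RELN
Keuschnigg,LEC,GMFG
Keuschnigg,LEC,FABP4
Keuschnigg,LEC,PPARG
Keuschnigg,LEC,MGP
Keuschnigg,LEC,CEACAM1
Keuschnigg,LEC,PVRL3
Keuschnigg,LEC,TNFSF10
Keuschnigg,LEC,HSD17B2
Keuschnigg,LEC,CD36
Keuschnigg,LEC,ID1
Keuschnigg,LEC,ADRB1
Keuschnigg,LEC,NID1
Keuschnigg,LEC,LAYN
Keuschnigg,LEC,ADAMTSL3
Keuschnigg,LEC,SNAI2
Keuschnigg,LEC,EPS8
Keuschnigg,LEC,AK5
Keuschnigg,LEC,RP11-65D13.1
Keuschnigg,LEC,FDFT1
Keuschnigg,LEC,GRAMD3
Keuschnigg,LEC,COLEC12
Keuschnigg,LEC,GHR
Keuschnigg,LEC,HEY1
Keuschnigg,LEC,GYPC
Keuschnigg,LEC,TFPI
Petrova,LEC,PROX1
Petrova,LEC,PDPN
Petrova,LEC,RELN
Petrova,LEC,GMFG
Petrova,LEC,FABP4
Petrova,LEC,PPARG
Petrova,LEC,MGP
Petrova,LEC,CXCL12
Petrova,LEC,MRC1
Petrova,LEC,MRC1L1
Petrova,LEC,CALCRL
Petrova,LEC,TFF3
Petrova,LEC,ANGPT2
Petrova,LEC,DSP
Petrova,LEC,SNRNP48
Petrova,LEC,RBP1
Petrova,LEC,MAF
Petrova,LEC,CH25H
Petrova,LEC,SEPP1
Petrova,LEC,SLC26A4
Petrova,LEC,RGS16
Petrova,LEC,ITGA9
Petrova,LEC,CDKN1C
Petrova,LEC,CRMP1
Petrova,LEC,PCSK6
Petrova,LEC,ITGA1
Petrova,LEC,MEF2C
Petrova,LEC,APOD
Petrova,LEC,PDLIM3
Petrova,LEC,CCNE2
Petrova,LEC,TIMP3
Petrova,LEC,CD200
Petrova,LEC,ADD3
Petrova,LEC,TK1
Petrova,LEC,LIPA
Hirakawa,LEC,PROX1
Hirakawa,LEC,PDPN
Hirakawa,LEC,RELN
Hirakawa,LEC,CEACAM1
Hirakawa,LEC,CXCL12
Hirakawa,LEC,MRC1
Hirakawa,LEC,MRC1L1
Hirakawa,LEC,CALCRL
Hirakawa,LEC,TFF3
Hirakawa,LEC,ANGPT2
Hirakawa,LEC,DSP
Hirakawa,LEC,SNRNP48
Hirakawa,LEC,F2RL1
Hirakawa,LEC,LGALS8
Hirakawa,LEC,PSMG1
Hirakawa,LEC,CCL5
Hirakawa,LEC,JUP
Hirakawa,LEC,GLRB
Hirakawa,LEC,THBS1
Hirakawa,LEC,HMMR
Hirakawa,LEC,IL6ST
Hirakawa,LEC,JAG1
Hirakawa,LEC,CCL20
Hirakawa,LEC,TGFA
Hirakawa,LEC,FGF12
Hirakawa,LEC,ITGA6
Hirakawa,LEC,MFAP3
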