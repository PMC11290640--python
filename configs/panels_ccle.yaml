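# Cell-line screening panels: per cancer, the drug list, Cancer Gene Census
# driver genes, and the drug-response measures screened.
panels:
  - cancer: BRCA
    drugs: [fulvestrant, doxorubicin, ixabepilone, docetaxel, capecitabine,
            paclitaxel, aminoglutethimide, carmofur, everolimus, palbociclib,
            cyclophosphamide, exemestane, epirubicin, raloxifene, anastrozole,
            5-fluorouracil, formestane, lapatinib, toremifene, letrozole,
            abemaciclib, gemcitabine, tamoxifen, ribociclib, vindesine]
    driver_genes: [AKT1, ARID1A, ARID1B, BAP1, BARD1, BRCA2, CASP8, CCND1,
                   CDH1, CDKN1B, CTCF, EP300, ERBB2, ESR1, ETV6, FOXA1, GATA3,
                   IKZF3, IRS4, KEAP1, MAP2K4, MAP3K1, MAP3K13, NCOR1, NOTCH1,
                   NTRK3, PBRM1, PIK3CA, PPM1D, RB1, SALL4, TBX3, TP53]
    measures: [AUC, EC50, LFC]
  - cancer: NSCLC
    drugs: [erlotinib, docetaxel, etoposide, vinorelbine, paclitaxel,
            alectinib, afatinib, gefitinib, crizotinib, osimertinib,
            gemcitabine, icotinib, brigatinib, vindesine]
    driver_genes: [AKT1, ALK, BAP1, BRAF, CCDC6, CD74, DDR2, DROSHA, EGFR,
                   EML4, ERBB2, ERBB4, EZR, FGFR2, HIP1, KDR, KEAP1, KIF5B,
                   LRIG3, MAP2K1, MAP2K2, NFE2L2, NKX2-1, NRG1, PIK3CB,
                   PTPN13, RET, ROS1, SDC4, SLC34A2, SMARCA4, SOX2, STK11,
                   TFG, TPM3, TPR]
    measures: [AUC, EC50, LFC]
  - cancer: CRC
    drugs: [floxuridine, regorafenib, capecitabine, carmofur, 5-fluorouracil,
            SN-38, ftorafur, doxifluridine, tipiracil, irinotecan, oxaliplatin]
    driver_genes: [AKT1, APC, AXIN1, AXIN2, B2M, BAX, BCL9L, BRAF, CTNNB1,
                   CUX1, EIF3E, EP300, FBXW7, GRIN2A, HIF1A, IKZF3, KRAS,
                   MAP2K1, MAP2K4, MDM2, MLH1, MSH2, MSH6, NTRK2, PIK3CA,
                   PIK3R1, POLE, PTPRK, PTPRT, QKI, RAD21, RSPO2, RSPO3,
                   SALL4, SFRP4, SMAD2, SMAD3, SMAD4, SRC, TBL1XR1, TCF7L2,
                   TGFBR2, TP53, UBR5]
    measures: [AUC, EC50, LFC]
  - cancer: PRAD
    drugs: [estramustine-phosphate, estramustine, nilutamide, bicalutamide,
            docetaxel, cabazitaxel, flutamide, abiraterone-acetate,
            mitoxantrone, enzalutamide, cyproterone-acetate, abiraterone]
    driver_genes: [ACSL3, AR, AXIN1, BRAF, CANT1, DDX5, ELK4, ERG, ETV1, ETV4,
                   ETV5, FOXA1, HERPUD1, HNRNPA2B1, KLF6, KLK2, NCOR2, NDRG1,
                   PTEN, RAF1, SALL4, SLC45A3, SPOP, TMPRSS2, ZFHX3]
    measures: [AUC, EC50]
  - cancer: SKCM
    drugs: [dabrafenib, vemurafenib, dacarbazine, trametinib, cobimetinib,
            vindesine]
    driver_genes: [ATF1, B2M, BAP1, BRAF, CDKN2A, CUX1, ERBB4, FAT4, GNA11,
                   GNAQ, GRIN2A, IRS4, KIT, MAP2K1, MAP2K2, MITF, NFKBIE,
                   NRAS, PPP6C, PREX2, PTPRT, RAC1, SALL4, SFRP4, STAG2, TERT,
                   TRRAP]
    measures: [AUC, EC50, LFC]
  - cancer: CML
    drugs: [bosutinib, hydroxyurea, busulfan, dasatinib, decitabine,
            cyclophosphamide, homoharringtonine, ponatinib, imatinib,
            nilotinib, mechlorethamine]
    driver_genes: [ABL1, BCR, CCDC6, CSF3R, ETNK1, GATA2, HOXA11, JAK2, MECOM,
                   MSI2, PCM1, PDGFRB, RPL22, SETBP1]
    measures: [AUC, EC50]
  - cancer: GB
    drugs: [carmustine, temozolomide]
    driver_genes: [DAXX, GOPC, HIF1A, IDH1, IDH2, LZTR1, MDM4, PDGFRA, PIK3CA,
                   PIK3R1, ROS1, SALL4, STAG2, TERT]
    measures: [AUC, EC50]
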