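drug_code,drug_name,had_group,had_type
Norepinephrine,Norepinephrine,general,ANS
Dopamine,Dopamine,general,ANS
Dobutamine,Dobutamine,general,ANS
Calcium gluconate,Calcium gluconate,general,END
Digoxin,Digoxin,general,CVS
Isoproterenol,Isoproterenol,general,ANS
Warfarin,Warfarin,general,BIG
Magnesium sulfate,Magnesium sulfate,general,CVS
Heparin,Heparin,general,BIG
Potassium chloride,Potassium chloride,general,CVS
Regular insulin,Regular insulin,general,END
Adrenaline,Adrenaline,general,ANS
Ketamine,Ketamine,narcotic_psychotropic,CNS
Midazolam,Midazolam,narcotic_psychotropic,CNS
Pethidine,Pethidine,narcotic_psychotropic,CNS
Alprazolam,Alprazolam,narcotic_psychotropic,CNS
Phentermine,Phentermine,narcotic_psychotropic,ANS
Oxycodone,Oxycodone,narcotic_psychotropic,CNS
Ephedrine,Ephedrine,narcotic_psychotropic,ANS
Nitrazepam,Nitrazepam,narcotic_psychotropic,CNS
Fentanyl,Fentanyl,narcotic_psychotropic,CNS
Methylphenidate HCL,Methylphenidate HCL,narcotic_psychotropic,ANS
Methadone,Methadone,narcotic_psychotropic,CNS
Pseudoephedrine,Pseudoephedrine,narcotic_psychotropic,ANS
Zolpidem,Zolpidem,narcotic_psychotropic,CNS
Morphine,Morphine,narcotic_psychotropic,CNS
5-Fluorouracil,5-Fluorouracil,iv_cytotoxic,Tumor
Arsenic trioxide,Arsenic trioxide,iv_cytotoxic,Tumor
Azacitidine,Azacitidine,iv_cytotoxic,Tumor
Bendamustine,Bendamustine,iv_cytotoxic,Tumor
Bleomycin,Bleomycin,iv_cytotoxic,Tumor
Busulfan,Busulfan,iv_cytotoxic,Tumor
Cabazitaxel,Cabazitaxel,iv_cytotoxic,Tumor
Carboplatin,Carboplatin,iv_cytotoxic,Tumor
Carmustine,Carmustine,iv_cytotoxic,Tumor
Cisplatin,Cisplatin,iv_cytotoxic,Tumor
Clofarabine,Clofarabine,iv_cytotoxic,Tumor
Cyclophosphamide,Cyclophosphamide,iv_cytotoxic,Tumor
Cytarabine,Cytarabine,iv_cytotoxic,Tumor
Dacarbazine,Dacarbazine,iv_cytotoxic,Tumor
Dactinomycin,Dactinomycin,iv_cytotoxic,Tumor
Decitabine,Decitabine,iv_cytotoxic,Tumor
Docetaxel,Docetaxel,iv_cytotoxic,Tumor
Doxorubicin,Doxorubicin,iv_cytotoxic,Tumor
Epirubicin,Epirubicin,iv_cytotoxic,Tumor
Eribulin mesylate,Eribulin mesylate,iv_cytotoxic,Tumor
Etoposide,Etoposide,iv_cytotoxic,Tumor
Fludarabine,Fludarabine,iv_cytotoxic,Tumor
Gemcitabine,Gemcitabine,iv_cytotoxic,Tumor
Idarubicin,Idarubicin,iv_cytotoxic,Tumor
Ifosfamide,Ifosfamide,iv_cytotoxic,Tumor
Irinotecan,Irinotecan,iv_cytotoxic,Tumor
Ixabepilone,Ixabepilone,iv_cytotoxic,Tumor
L-Asparaginase,L-Asparaginase,iv_cytotoxic,Tumor
Liposomal-doxorubicin,Liposomal-doxorubicin,iv_cytotoxic,Tumor
Melphalan,Melphalan,iv_cytotoxic,Tumor
Methotrexate,Methotrexate,iv_cytotoxic,Tumor
Mitomycin C,Mitomycin C,iv_cytotoxic,Tumor
Mitoxantrone,Mitoxantrone,iv_cytotoxic,Tumor
Oxaliplatin,Oxaliplatin,iv_cytotoxic,Tumor
Paclitaxel,Paclitaxel,iv_cytotoxic,Tumor
Paclitaxel (polymeric micelle),Paclitaxel (polymeric micelle),iv_cytotoxic,Tumor
Pemetrexed,Pemetrexed,iv_cytotoxic,Tumor
Topotecan,Topotecan,iv_cytotoxic,Tumor
Vinblastine,Vinblastine,iv_cytotoxic,Tumor
Vincristine sulfate,Vincristine sulfate,iv_cytotoxic,Tumor
Vinorelbine,Vinorelbine,iv_cytotoxic,Tumor
Temozolomide,Temozolomide,oral_cytotoxic,Tumor
Methotrexate (oral),Methotrexate,oral_cytotoxic,Tumor
Melphalan (oral),Melphalan,oral_cytotoxic,Tumor
Tegafur-Uracil,Tegafur-Uracil,oral_cytotoxic,Tumor
Tegafur-Gimeracil-Oteracil,Tegafur-Gimeracil-Oteracil,oral_cytotoxic,Tumor
Cyclophosphamide (oral),Cyclophosphamide,oral_cytotoxic,Tumor
Capecitabine,Capecitabine,oral_cytotoxic,Tumor
Hydroxyurea,Hydroxyurea,oral_cytotoxic,Tumor
Fludarabine phosphate,Fludarabine phosphate,oral_cytotoxic,Tumor
Etoposide (oral),Etoposide,oral_cytotoxic,Tumor
Topotecan (oral),Topotecan,oral_cytotoxic,Tumor
Mercaptopurine,Mercaptopurine,oral_cytotoxic,Tumor
Vinorelbine (oral),Vinorelbine,oral_cytotoxic,Tumor
Thioguanine,Thioguanine,oral_cytotoxic,Tumor
Chlorambucil,Chlorambucil,oral_cytotoxic,Tumor
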