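locus,allele,frequency,population
mh01zha018,TC,0.24,Shandong_Han
mh01zha018,CC,0.34,Shandong_Han
mh01zha018,GT,0.11,Shandong_Han
mh01zha018,GC,0.30,Shandong_Han
mh01zha034,TC,0.14,Shandong_Han
mh01zha034,CT,0.33,Shandong_Han
mh01zha034,CC,0.35,Shandong_Han
mh01zha034,CG,0.18,Shandong_Han
mh03zha016,AT,0.17,Shandong_Han
mh03zha016,TC,0.01,Shandong_Han
mh03zha016,CT,0.32,Shandong_Han
mh03zha016,CC,0.21,Shandong_Han
mh03zha016,GT,0.29,Shandong_Han
mh04zha007,AAT,0.40,Shandong_Han
mh04zha007,AAC,0.18,Shandong_Han
mh04zha007,CAC,0.17,Shandong_Han
mh04zha007,GGC,0.26,Shandong_Han
mh04zha012,AT,0.36,Shandong_Han
mh04zha012,AC,0.23,Shandong_Han
mh04zha012,TC,0.19,Shandong_Han
mh04zha012,CC,0.22,Shandong_Han
mh04zha020,TC,0.24,Shandong_Han
mh04zha020,CT,0.41,Shandong_Han
mh04zha020,CC,0.18,Shandong_Han
mh04zha020,GT,0.01,Shandong_Han
mh04zha020,GC,0.17,Shandong_Han
mh04zha027a,AGT,0.11,Shandong_Han
mh04zha027a,CAT,0.21,Shandong_Han
mh04zha027a,CGT,0.19,Shandong_Han
mh04zha027a,CGC,0.39,Shandong_Han
mh04zha027a,CGG,0.10,Shandong_Han
mh04zha031,TA,0.16,Shandong_Han
mh04zha031,TG,0.33,Shandong_Han
mh04zha031,CG,0.34,Shandong_Han
mh04zha031,GG,0.17,Shandong_Han
mh04zha032a,TAAA,0.05,Shandong_Han
mh04zha032a,TAAG,0.01,Shandong_Han
mh04zha032a,TTCG,0.01,Shandong_Han
mh04zha032a,TGAA,0.02,Shandong_Han
mh04zha032a,TGAG,0.14,Shandong_Han
mh04zha032a,TGCA,0.02,Shandong_Han
mh04zha032a,TGCG,0.06,Shandong_Han
mh04zha032a,CAAA,0.47,Shandong_Han
mh04zha032a,CAAG,0.09,Shandong_Han
mh04zha032a,CACG,0.02,Shandong_Han
mh04zha032a,CTCG,0.03,Shandong_Han
mh04zha032a,CGAG,0.06,Shandong_Han
mh04zha032a,CGCG,0.05,Shandong_Han
mh05zha004a,TC,0.22,Shandong_Han
mh05zha004a,GA,0.35,Shandong_Han
mh05zha004a,GC,0.08,Shandong_Han
mh05zha004a,GG,0.35,Shandong_Han
mh06zha012a,ATA,0.35,Shandong_Han
mh06zha012a,ATC,0.30,Shandong_Han
mh06zha012a,ATG,0.02,Shandong_Han
mh06zha012a,GAG,0.15,Shandong_Han
mh06zha012a,GTG,0.18,Shandong_Han
mh06zha025,AC,0.37,Shandong_Han
mh06zha025,TC,0.23,Shandong_Han
mh06zha025,GT,0.10,Shandong_Han
mh06zha025,GC,0.30,Shandong_Han
mh06zha026,AC,0.17,Shandong_Han
mh06zha026,GA,0.33,Shandong_Han
mh06zha026,GC,0.36,Shandong_Han
mh06zha026,GG,0.14,Shandong_Han
mh07zha014,AT,0.32,Shandong_Han
mh07zha014,TT,0.23,Shandong_Han
mh07zha014,CT,0.31,Shandong_Han
mh07zha014,CC,0.14,Shandong_Han
mh07zha026,TTC,0.22,Shandong_Han
mh07zha026,TGA,0.23,Shandong_Han
mh07zha026,TGT,0.38,Shandong_Han
mh07zha026,TGC,0.10,Shandong_Han
mh07zha026,CGA,0.07,Shandong_Han
mh07zha027,TC,0.33,Shandong_Han
mh07zha027,CT,0.32,Shandong_Han
mh07zha027,CC,0.21,Shandong_Han
mh07zha027,GC,0.14,Shandong_Han
mh08zha007a,AA,0.34,Shandong_Han
mh08zha007a,TA,0.29,Shandong_Han
mh08zha007a,TC,0.24,Shandong_Han
mh08zha007a,CA,0.13,Shandong_Han
mh09zha012,AT,0.23,Shandong_Han
mh09zha012,GT,0.22,Shandong_Han
mh09zha012,GC,0.22,Shandong_Han
mh09zha012,GG,0.33,Shandong_Han
mh09zha017,TT,0.25,Shandong_Han
mh09zha017,TC,0.17,Shandong_Han
mh09zha017,TG,0.39,Shandong_Han
mh09zha017,CG,0.19,Shandong_Han
mh09zha021,AA,0.23,Shandong_Han
mh09zha021,AG,0.33,Shandong_Han
mh09zha021,TG,0.17,Shandong_Han
mh09zha021,GG,0.28,Shandong_Han
mh10zha010,AA,0.30,Shandong_Han
mh10zha010,AC,0.43,Shandong_Han
mh10zha010,AG,0.18,Shandong_Han
mh10zha010,GA,0.09,Shandong_Han
mh11zha006b,AAT,0.26,Shandong_Han
mh11zha006b,ATC,0.33,Shandong_Han
mh11zha006b,AGC,0.20,Shandong_Han
mh11zha006b,GGC,0.21,Shandong_Han
mh13zha003,TTT,0.04,Shandong_Han
mh13zha003,TTC,0.01,Shandong_Han
mh13zha003,TCT,0.11,Shandong_Han
mh13zha003,TCC,0.02,Shandong_Han
mh13zha003,TGT,0.18,Shandong_Han
mh13zha003,GTT,0.05,Shandong_Han
mh13zha003,GCT,0.14,Shandong_Han
mh13zha003,GGT,0.46,Shandong_Han
mh13zha008,TA,0.14,Shandong_Han
mh13zha008,TG,0.19,Shandong_Han
mh13zha008,CA,0.36,Shandong_Han
mh13zha008,GG,0.31,Shandong_Han
mh14zha003,CAT,0.10,Shandong_Han
mh14zha003,CCA,0.36,Shandong_Han
mh14zha003,CCT,0.05,Shandong_Han
mh14zha003,GCA,0.21,Shandong_Han
mh14zha003,GCG,0.29,Shandong_Han
mh14zha008,TA,0.05,Shandong_Han
mh14zha008,TG,0.10,Shandong_Han
mh14zha008,GA,0.26,Shandong_Han
mh14zha008,GC,0.11,Shandong_Han
mh14zha008,GG,0.48,Shandong_Han
mh14zha010,TGC,0.48,Shandong_Han
mh14zha010,GTG,0.12,Shandong_Han
mh14zha010,GGA,0.10,Shandong_Han
mh14zha010,GGC,0.05,Shandong_Han
mh14zha010,GGG,0.24,Shandong_Han
mh16zha013,TTT,0.39,Shandong_Han
mh16zha013,TTC,0.15,Shandong_Han
mh16zha013,TTG,0.07,Shandong_Han
mh16zha013,CTC,0.24,Shandong_Han
mh16zha013,CCC,0.15,Shandong_Han
mh18zha010a,ATGGA,0.28,Shandong_Han
mh18zha010a,CCAGG,0.09,Shandong_Han
mh18zha010a,CCGGG,0.39,Shandong_Han
mh18zha010a,GTAAG,0.13,Shandong_Han
mh18zha010a,GTAGG,0.01,Shandong_Han
mh18zha010a,GTGGA,0.11,Shandong_Han
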