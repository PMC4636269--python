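acaricide_class,target_protein,gene,accession,codon_position,wild_codon,mutant_codon,substituted_position_in_codon,wild_nt,mutant_nt,abbreviation,substitution_class,genetic_code
Organophosphate,AChE,Tuace,tetur19g00850,228,GGC,AGC,1,G,A,G228S,transition,1
Organophosphate,AChE,Tuace,tetur19g00850,228,GGC,GCC,2,G,C,G228A,transversion,1
Organophosphate,AChE,Tuace,tetur19g00850,309,GCT,TCT,1,G,T,A309S,transversion,1
Organophosphate,AChE,Tuace,tetur19g00850,391,GCA,ACA,1,G,A,A391T,transition,1
Organophosphate,AChE,Tuace,tetur19g00850,436,GGA,GCA,2,G,C,G436A,transversion,1
Organophosphate,AChE,Tuace,tetur19g00850,439,TTT,TGG,2,T,G,F439W,transversion,1
Organophosphate,AChE,Tuace,tetur19g00850,439,TTT,TAT,2,T,A,F439Y,transversion,1
Pyrethroid,VSSC,Tuvssc,Tetur34g00970,1022,CTC,GTC,1,C,G,L1022V,transversion,1
Pyrethroid,VSSC,Tuvssc,Tetur34g00970,1376,GCT,GAT,2,C,A,A1376D,transversion,1
Pyrethroid,VSSC,Tuvssc,Tetur34g00970,1704,TTC,ATC,1,T,A,F1704I,transversion,1
Abamectin,GluCl1,TuGluCl1,Tetur02g04080,323,GGT,GAT,2,G,A,G323D,transition,1
Abamectin,GluCl3,TuGluCl3,Tetur10g03090,326,GGA,GAA,2,G,A,G326E,transition,1
Etoxazole,CHS1,TuCHS,Tetur03g08510,1017,ATT,TTT,1,A,T,I1017F,transversion,1
Bifenazate,CytB,TuCytB,YP_001795379.1,126,GGA,AGA,1,G,A,G126S,transition,5
Bifenazate,CytB,TuCytB,YP_001795379.1,136,ATT,ACT,2,T,C,I136T,transition,5
Bifenazate,CytB,TuCytB,YP_001795379.1,141,TCT,TTT,2,C,T,S141F,transition,5
Bifenazate,CytB,TuCytB,YP_001795379.1,161,GAT,GGT,2,A,G,D161G,transition,5
Bifenazate,CytB,TuCytB,YP_001795379.1,262,CCT,ACT,1,C,A,P262T,transversion,5
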