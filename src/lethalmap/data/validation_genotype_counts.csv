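locus,sv_id,annotation,chrom,pos_bp,ref_allele,alt_allele,group,n_AA,n_AB,n_BB,n_missing
BH1,43566547,intergenic,7,43566547,G,T,Overall,599,152,4,13
BH1,43566547,intergenic,7,43566547,G,T,Carrier,98,26,1,2
BH1,43566547,intergenic,7,43566547,G,T,Normal,498,124,3,11
BH1,43566547,intergenic,7,43566547,G,T,Unknown,3,2,0,0
BH1,45578794,MBD3.intron,7,45578794,C,T,Overall,464,142,1,161
BH1,45578794,MBD3.intron,7,45578794,C,T,Carrier,76,20,1,30
BH1,45578794,MBD3.intron,7,45578794,C,T,Normal,387,120,0,129
BH1,45578794,MBD3.intron,7,45578794,C,T,Unknown,1,2,0,2
BH1,45581764,intergenic,7,45581764,G,C,Overall,623,128,3,14
BH1,45581764,intergenic,7,45581764,G,C,Carrier,105,20,1,1
BH1,45581764,intergenic,7,45581764,G,C,Normal,514,107,2,13
BH1,45581764,intergenic,7,45581764,G,C,Unknown,4,1,0,0
BH1,45599451,intergenic,7,45599451,T,C,Overall,1,125,624,18
BH1,45599451,intergenic,7,45599451,T,C,Carrier,1,20,103,3
BH1,45599451,intergenic,7,45599451,T,C,Normal,0,104,517,15
BH1,45599451,intergenic,7,45599451,T,C,Unknown,0,1,4,0
BH1,45613660,TCF3.exon4,7,45613660,T,C,Overall,1,129,610,28
BH1,45613660,TCF3.exon4,7,45613660,T,C,Carrier,1,20,101,5
BH1,45613660,TCF3.exon4,7,45613660,T,C,Normal,0,108,505,23
BH1,45613660,TCF3.exon4,7,45613660,T,C,Unknown,0,1,4,0
BH1,45616897,TCF3.intron,7,45616897,T,C,Overall,1,129,625,13
BH1,45616897,TCF3.intron,7,45616897,T,C,Carrier,1,21,103,2
BH1,45616897,TCF3.intron,7,45616897,T,C,Normal,0,107,518,11
BH1,45616897,TCF3.intron,7,45616897,T,C,Unknown,0,1,4,0
BH1,45765465,REXO1.exon16,7,45765465,T,C,Overall,1,127,624,16
BH1,45765465,REXO1.exon16,7,45765465,T,C,Carrier,1,21,103,2
BH1,45765465,REXO1.exon16,7,45765465,T,C,Normal,0,105,517,14
BH1,45765465,REXO1.exon16,7,45765465,T,C,Unknown,0,1,4,0
BH1,45769444,REXO1.intron,7,45769444,DEL,A,Overall,623,129,1,15
BH1,45769444,REXO1.intron,7,45769444,DEL,A,Carrier,103,21,1,2
BH1,45769444,REXO1.intron,7,45769444,DEL,A,Normal,516,107,0,13
BH1,45769444,REXO1.intron,7,45769444,DEL,A,Unknown,4,1,0,0
BH1,45772444,REXO1.exon3,7,45772444,C,G,Overall,3,128,622,15
BH1,45772444,REXO1.exon3,7,45772444,C,G,Carrier,1,21,103,2
BH1,45772444,REXO1.exon3,7,45772444,C,G,Normal,2,106,515,13
BH1,45772444,REXO1.exon3,7,45772444,C,G,Unknown,0,1,4,0
HH2,95643514,NCEH1_BOVIN.exon5,1,95643514,A,G,Overall,596,167,1,4
HH2,95643514,NCEH1_BOVIN.exon5,1,95643514,A,G,Carrier,0,122,1,0
HH2,95643514,NCEH1_BOVIN.exon5,1,95643514,A,G,Homozygous,1,1,0,0
HH2,95643514,NCEH1_BOVIN.exon5,1,95643514,A,G,Normal,595,44,0,4
HH2,95649010,NCEH1_BOVIN.exon5,1,95649010,C,T,Overall,597,166,1,4
HH2,95649010,NCEH1_BOVIN.exon5,1,95649010,C,T,Carrier,0,122,1,0
HH2,95649010,NCEH1_BOVIN.exon5,1,95649010,C,T,Homozygous,1,1,0,0
HH2,95649010,NCEH1_BOVIN.exon5,1,95649010,C,T,Normal,596,43,0,4
HH2,96677430,intergenic,1,96677430,G,A,Overall,490,87,0,191
HH2,96677430,intergenic,1,96677430,G,A,Carrier,1,75,0,47
HH2,96677430,intergenic,1,96677430,G,A,Homozygous,0,0,0,2
HH2,96677430,intergenic,1,96677430,G,A,Normal,489,12,0,142
HH3,95380670,SMC2.intron,8,95380670,A,G,Overall,395,355,12,6
HH3,95380670,SMC2.intron,8,95380670,A,G,Normal,395,47,1,3
HH3,95380670,SMC2.intron,8,95380670,A,G,Homozygous,0,2,0,2
HH3,95380670,SMC2.intron,8,95380670,A,G,Carrier,0,306,11,1
HH3,95394960,SMC2.intron,8,95394960,DEL,T,Overall,371,355,36,6
HH3,95394960,SMC2.intron,8,95394960,DEL,T,Normal,371,69,4,2
HH3,95394960,SMC2.intron,8,95394960,DEL,T,Homozygous,0,2,0,2
HH3,95394960,SMC2.intron,8,95394960,DEL,T,Carrier,0,284,32,2
HH3,95396031,SMC2.exon19,8,95396031,C,T,Overall,346,362,30,30
HH3,95396031,SMC2.exon19,8,95396031,C,T,Normal,346,72,1,27
HH3,95396031,SMC2.exon19,8,95396031,C,T,Homozygous,0,2,0,2
HH3,95396031,SMC2.exon19,8,95396031,C,T,Carrier,0,288,29,1
HH3,95399455,SMC2.intron,8,95399455,C,T,Overall,371,362,30,5
HH3,95399455,SMC2.intron,8,95399455,C,T,Normal,371,72,1,2
HH3,95399455,SMC2.intron,8,95399455,C,T,Homozygous,0,2,0,2
HH3,95399455,SMC2.intron,8,95399455,C,T,Carrier,0,288,29,1
HH3,95401269,SMC2.intron,8,95401269,A,G,Overall,371,362,30,5
HH3,95401269,SMC2.intron,8,95401269,A,G,Normal,371,72,1,2
HH3,95401269,SMC2.intron,8,95401269,A,G,Homozygous,0,2,0,2
HH3,95401269,SMC2.intron,8,95401269,A,G,Carrier,0,288,29,1
HH3,95403969,SMC2.intron,8,95403969,G,T,Overall,371,360,30,5
HH3,95403969,SMC2.intron,8,95403969,G,T,Normal,371,72,1,2
HH3,95403969,SMC2.intron,8,95403969,G,T,Homozygous,0,2,0,2
HH3,95403969,SMC2.intron,8,95403969,G,T,Carrier,0,286,29,1
HH3,95404031,SMC2.exon22,8,95404031,C,T,Overall,371,362,30,5
HH3,95404031,SMC2.exon22,8,95404031,C,T,Normal,371,72,1,2
HH3,95404031,SMC2.exon22,8,95404031,C,T,Homozygous,0,2,0,2
HH3,95404031,SMC2.exon22,8,95404031,C,T,Carrier,0,288,29,1
HH3,95404125,SMC2.intron,8,95404125,A,C,Overall,371,362,30,5
HH3,95404125,SMC2.intron,8,95404125,A,C,Normal,371,72,1,2
HH3,95404125,SMC2.intron,8,95404125,A,C,Homozygous,0,2,0,2
HH3,95404125,SMC2.intron,8,95404125,A,C,Carrier,0,288,29,1
HH3,95406982,SMC2.intron,8,95406982,DEL,,Overall,754,0,0,14
HH3,95406982,SMC2.intron,8,95406982,DEL,,Normal,444,0,0,2
HH3,95406982,SMC2.intron,8,95406982,DEL,,Homozygous,2,0,0,2
HH3,95406982,SMC2.intron,8,95406982,DEL,,Carrier,308,0,0,10
HH3,95407106,SMC2.exon23,8,95407106,T,C,Overall,371,355,24,17
HH3,95407106,SMC2.exon23,8,95407106,T,C,Normal,371,71,1,3
HH3,95407106,SMC2.exon23,8,95407106,T,C,Homozygous,0,2,0,2
HH3,95407106,SMC2.exon23,8,95407106,T,C,Carrier,0,282,23,12
HH3,95410507,SMC2.exon24,8,95410507,T,C,Overall,445,318,0,4
HH3,95410507,SMC2.exon24,8,95410507,T,C,Normal,445,0,0,1
HH3,95410507,SMC2.exon24,8,95410507,T,C,Homozygous,0,2,0,2
HH3,95410507,SMC2.exon24,8,95410507,T,C,Carrier,0,316,0,1
HH3,95411823,intergenic,8,95411823,T,C,Overall,362,368,31,7
HH3,95411823,intergenic,8,95411823,T,C,Normal,362,81,1,2
HH3,95411823,intergenic,8,95411823,T,C,Homozygous,0,2,0,2
HH3,95411823,intergenic,8,95411823,T,C,Carrier,0,285,30,3
HH3,95412363,intergenic,8,95412363,T,G,Overall,370,362,30,6
HH3,95412363,intergenic,8,95412363,T,G,Normal,370,72,1,3
HH3,95412363,intergenic,8,95412363,T,G,Homozygous,0,2,0,2
HH3,95412363,intergenic,8,95412363,T,G,Carrier,0,288,29,1
HH3,95412695,intergenic,8,95412695,T,A,Overall,371,362,30,5
HH3,95412695,intergenic,8,95412695,T,A,Normal,371,72,1,2
HH3,95412695,intergenic,8,95412695,T,A,Homozygous,0,2,0,2
HH3,95412695,intergenic,8,95412695,T,A,Carrier,0,288,29,1
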