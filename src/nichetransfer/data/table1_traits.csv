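aou,common_name,species_name,range_class,migratory,habitat,conservation,trend,trend_alt,audubon_decline,mass_cat
AOU 10,Common Loon,Gavia immer,WC,T,E,LC,decreasing,decreasing,0,4
AOU 172,Northern Pintail,Anas acuta,WC,T,E,LC,decreasing,decreasing,1,3
AOU 240,Broad-winged Hawk,Buteo platypterus,WC,N,W,LC,increasing,increasing,0,2
AOU 242,Swainson's Hawk,Buteo swainsoni,WC,N,G,LC,stable,stable,0,3
AOU 251,Golden Eagle,Aquila chrysaetos,WR,T,G,LC,stable,stable,0,4
AOU 271,Prairie Falcon,Falco mexicanus,WC,T,G,LC,stable,stable,0,3
AOU 295,Greater Sage Grouse,Centrocercus urophasianus,NER,R,S,NT,decreasing,decreasing,0,4
AOU 302,Greater Prairie Chicken,Tympanuchus cupido,NER,R,G,V,decreasing,decreasing,0,3
AOU 335,Clapper Rail,Rallus longirostris,WR,R,E,LC,decreasing,decreasing,0,2
AOU 360,Sandhill Crane,Grus Canadensis,WC,T,E,LC,increasing,increasing,0,4
AOU 376,Piping Plover,Charadrius melodus,NER,T,B,NT,increasing,increasing,0,1
AOU 379,Mountain Plover,Charadrius montanus,NER,N,G,NT,decreasing,decreasing,0,1
AOU 382,American Oystercatcher,Haematopus palliates,WR,R,E,LC,stable,stable,0,3
AOU 412,Long-billed Curlew,Numenius americanus,WC,N,G,LC,decreasing,decreasing,0,2
AOU 691,Burrowing Owl,Athene cunicularia,WR,N,G,LC,decreasing,decreasing,0,2
AOU 939,Lewis' woodpecker,Melanerpe lewis,WR,T,E,LC,decreasing,decreasing,0,2
AOU 971,Black backed woodpecker,Picoides arcticus,WR,R,W,LC,stable,stable,0,1
AOU 1203,Eastern Kingbird,Tyrannus tyrannus,WC,N,G,LC,decreasing,decreasing,0,1
AOU 1252,Loggerhead Shrike,Lanius ludovicianus,WC,T,W,LC,decreasing,decreasing,1,1
AOU 1317,Yellow-billed Magpie,Pica nuttalli,NEC,R,W,LC,stable,stable,0,2
AOU 1341,Tree Swallow,Tachycineta bicolor,WC,T,E,LC,stable,stable,0,2
AOU 1361,Boreal Chickadee,Poecile hudsonicus,WR,R,W,LC,decreasing,decreasing,1,1
AOU 1370,White-breasted Nuthatch,Sitta carolinensis,WC,R,W,LC,increasing,increasing,0,1
AOU 1372,Brown-headed Nuthatch,Sitta pusilla,NEC,R,W,LC,stable,stable,0,1
AOU 1425,Ruby-crowned Kinglet,Regulus calendula,WC,T,W,LC,increasing,increasing,0,1
AOU 1483,Wood thrush,Hylocichla mustelina,WR,N,W,LC,decreasing,decreasing,0,1
AOU 1575,Yellow Warbler,Dendroica petechial,WC,N,S,LC,stable,stable,0,1
AOU 1595,Palm Warbler,Dendroica palmarum,WC,N,S,LC,increasing,increasing,0,1
AOU 1804,Brewer's Sparrow,Spizella breweri,WC,N,S,LC,decreasing,decreasing,0,1
AOU 1805,Field Sparrow,Spizella pusilla,WC,T,S,LC,increasing,decreasing,1,1
AOU 1814,Grasshopper Sparrow,Ammodramus savannarum,WR,N,G,LC,decreasing,decreasing,1,1
AOU 1837,Chestnut-collared Longspur,Calcarius ornatus,NER,T,G,NT,decreasing,decreasing,0,1
AOU 1880,Eastern Meadowlark,Sturnella magna,WC,T,G,LC,increasing,decreasing,1,1
AOU 1916,Baltimore Oriole,Icterus galbula,WC,N,W,LC,stable,stable,0,1
AOU 1931,Black Rosy-Finch,Leucosticte atrata,NER,T,O,LC,stable,stable,0,1
AOU 1958,Evening Grosbeak,Coccothraustes vespertinus,WC,T,W,LC,decreasing,decreasing,1,1
AOU sms,Saltmarsh Sparrow,Ammodramus caudacutus,NER,T,E,V,decreasing,decreasing,0,1
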