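x,y,yhat
-0.5,0.52437736638035437,0.51483472359983184
-0.48999999999999999,0.3231106142078975,0.4013094870018788
-0.47999999999999998,0.3759738193221776,0.2936541604051412
-0.46999999999999997,0.30733177982179849,0.19717034626619503
-0.46000000000000002,0.0016436319433488777,0.11112894632260802
-0.45000000000000001,-0.0086828577364592846,0.03425093741680809
-0.44,0.057813706020372821,-0.0091249102025927169
-0.42999999999999999,-0.009590987951802115,-0.015083196974147874
-0.41999999999999998,-0.00035745681447888313,-0.0073830504989816749
-0.41000000000000003,-0.064300864863125348,0.006390571216426306
-0.40000000000000002,0.094823579841449526,0.042980391861742143
-0.39000000000000001,0.12407001481238408,0.10807290521668275
-0.38,0.12002583441700265,0.17368288655793118
-0.37,0.27146730168309802,0.22428041673172788
-0.35999999999999999,0.2965239103293062,0.27651739407747233
-0.34999999999999998,0.27674810578186732,0.33992183219275429
-0.33999999999999997,0.46683344594444826,0.4198427114433172
-0.32999999999999996,0.45468465169833716,0.52284946292758339
-0.32000000000000001,0.69462096768700898,0.62405033176261182
-0.31,0.70889557290363625,0.70994699683428042
-0.29999999999999999,0.77910363706261587,0.79679192362531193
-0.29000000000000004,0.81000995015839017,0.87041727978820171
-0.28000000000000003,1.0199672698449298,0.92481927382345575
-0.27000000000000002,0.95252588437862151,0.96555825477505608
-0.26000000000000001,0.95687739959129581,0.98678518369279755
-0.25,0.97182931596094169,0.99307825871861688
-0.23999999999999999,1.0337283602086123,0.99377179434148122
-0.22999999999999998,0.99412376809325187,0.99386148466099977
-0.21999999999999997,0.95518257167868648,0.98114367783638512
-0.21000000000000002,0.89894999395133635,0.93343250748113249
-0.20000000000000001,0.96522443421587334,0.84477212365103826
-0.19,0.68037644447176704,0.72752168806783701
-0.17999999999999999,0.58336552525670438,0.60977721410636909
-0.16999999999999998,0.46629344150482621,0.51829000872912367
-0.15999999999999998,0.48661173702388721,0.45149583073206673
-0.14999999999999997,0.43580928623019738,0.36957466990551502
-0.14000000000000001,0.25000736633675241,0.26013200007300108
-0.13,0.11407548696865283,0.156860454919655
-0.12,0.048784881356806212,0.093945414664128798
-0.10999999999999999,0.11389408300404424,0.07114183692173788
-0.099999999999999978,0.083932075548698498,0.055249369206939514
-0.089999999999999969,0.047394990807176664,0.032007145049914358
-0.080000000000000016,-0.052254140797231327,0.008633944110078496
-0.070000000000000007,0.03428132528102204,0.012729415863271976
-0.059999999999999998,0.056921338498248472,0.057313556050887386
-0.049999999999999989,0.11298659055084742,0.12565281155150007
-0.03999999999999998,0.22744074927151098,0.19857459523452411
-0.029999999999999971,0.24997424641247654,0.27126455552375089
-0.020000000000000018,0.37025080870341248,0.35423162915180728
-0.010000000000000009,0.41171566826624889,0.43915697843034901
0,0.52312955189519872,0.51339765161300566
0.010000000000000009,0.64419371535994563,0.58263965011577246
0.020000000000000018,0.56748981075388583,0.65151908454334651
0.030000000000000027,0.74233970018091444,0.71302770472023325
0.040000000000000036,0.80464374062092092,0.78962039936381323
0.050000000000000044,0.85339826932800655,0.88293537387616439
0.060000000000000053,0.93040214613487526,0.95812373418924512
0.070000000000000062,1.1038868854630675,1.0060028160081722
0.07999999999999996,0.92974687495867636,1.0122491233701036
0.089999999999999969,1.0735196190245575,0.9773005155363651
0.099999999999999978,0.8408986764183124,0.93409455173297284
0.10999999999999999,0.91136253762306985,0.90575500232424588
0.12,0.89827686659629502,0.88518989595438102
0.13,0.86560978138308708,0.85878439409517593
0.14000000000000001,0.797774963434286,0.79045055498000028
0.15000000000000002,0.71797627600346758,0.68352098949764761
0.16000000000000003,0.53476861100227679,0.57979690125963934
0.17000000000000004,0.43161659682217773,0.47670876386947164
0.18000000000000005,0.4442931269181446,0.36782674736518362
0.19000000000000006,0.27180600822693401,0.25517179795319872
0.20000000000000007,0.10405246798672918,0.1452502562816807
0.20999999999999996,0.044852709169016042,0.060378423095298159
0.21999999999999997,0.0042798543688636614,0.02731137853351923
0.22999999999999998,0.074884616580175561,0.029679351760015064
0.23999999999999999,0.020250433521300862,0.028310799512634467
0.25,0.055238828325421457,0.023397322836639877
0.26000000000000001,-0.025323837071267105,0.025847001743703732
0.27000000000000002,0.047794932342011522,0.047293664968671517
0.28000000000000003,0.12788326876637945,0.091757072882096335
0.29000000000000004,0.11076796311167549,0.14662178377426585
0.30000000000000004,0.24264939285835663,0.20489126559383342
0.31000000000000005,0.23415627893213178,0.26441276850953366
0.32000000000000006,0.34661074869236747,0.33557451839948443
0.33000000000000007,0.43806570871547751,0.42430121039707069
0.33999999999999997,0.4669994451350285,0.52420978929101725
0.34999999999999998,0.69346629565032014,0.62731543407324009
0.35999999999999999,0.70332464983463949,0.7311659323819415
0.37,0.81971152437255967,0.83092632430530977
0.38,0.92371635410036734,0.91328195003956802
0.39000000000000001,0.97387583410432721,0.97326266906617065
0.40000000000000002,1.0287590668653996,1.0066917890494507
0.41000000000000003,0.98817851189648509,1.0084253606064955
0.42000000000000004,0.96514949925060345,0.97759312232544193
0.43000000000000005,0.97791412369180364,0.9229239626095983
0.44000000000000006,0.81742677151636722,0.85672006387537014
0.45000000000000007,0.78873949939362631,0.79418377918888827
0.45999999999999996,0.73645758397599259,0.74621995241407835
0.46999999999999997,0.68813365128138004,0.69471497358398338
0.47999999999999998,0.71604421448021394,0.63121712197723678
0.48999999999999999,0.52125233286405803,0.55855803541844162
0.5,0.46974699567684902,0.4738047748214646
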