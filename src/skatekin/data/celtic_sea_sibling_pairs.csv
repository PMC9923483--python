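id1,year1,lat1,lon1,sex1,length1,id2,year2,lat2,lon2,sex2,length2,kinship,distance_km
elasm_1232,2015,49.32 N,6.73 W,M,121,elasm_1401,2017,49.20 N,7.82 W,F,122,FS,80
elasm_1415,2017,49.35 N,7.55 W,F,142,elasm_608,2011,49.97 N,6.85 W,M,132,FS,85
elasm_1378,2017,49.09 N,7.93 W,F,94,elasm_1388,2017,49.27 N,7.67 W,F,84,FS,27
elasm_1351,2017,50.23 N,7.01 W,M,97,elasm_1354,2017,50.23 N,7.01 W,M,115,HS,0
elasm_1078,2015,49.50 N,6.60 W,F,136,elasm_749,2011,50.03 N,6.92 W,F,141,HS,63
elasm_1315,2017,50.11 N,6.80 W,M,120,elasm_918,2014,49.95 N,6.83 W,M,117,HS,17
elasm_1338,2017,50.18 N,6.98 W,M,113,elasm_1339,2017,50.18 N,6.98 W,M,129,HS,0
elasm_1234,2015,49.32 N,6.73 W,M,74,elasm_1291,2017,49.73 N,7.22 W,F,78,HS,57
elasm_612,2011,49.97 N,6.85 W,F,127,elasm_918,2014,49.95 N,6.83 W,M,117,HS,2
elasm_744,2011,50.03 N,6.92 W,M,107,elasm_747,2011,50.03 N,6.92 W,M,123,HS,0
elasm_645,2011,49.97 N,6.85 W,F,122,elasm_956,2014,49.83 N,7.02 W,M,127,HS,19
elasm_884,2014,49.89 N,6.97 W,M,125,elasm_950,2014,49.83 N,7.02 W,F,123,HS,8
elasm_1309,2017,50.11 N,6.80 W,F,134,elasm_685,2011,49.45 N,7.40 W,M,121,HS,85
elasm_1245,2015,49.28 N,6.68 W,M,133,elasm_623,2011,49.97 N,6.85 W,F,123,HS,77
elasm_1311,2017,50.11 N,6.80 W,F,136,elasm_618,2011,49.97 N,6.85 W,F,139,HS,16
elasm_1277,2015,49.53 N,6.38 W,M,119,elasm_1357,2017,50.18 N,6.82 W,F,125,HS,78
elasm_1422,2017,49.48 N,7.44 W,M,125,elasm_744,2011,50.03 N,6.92 W,M,107,HS,72
elasm_1242,2015,49.28 N,6.68 W,F,105,elasm_1327,2017,50.11 N,7.02 W,F,127,HS,94
elasm_615,2011,49.97 N,6.85 W,F,132,elasm_651,2011,49.97 N,6.85 W,M,116,HS,0
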