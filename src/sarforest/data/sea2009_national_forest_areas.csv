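region_id,country,palsar,palsar_modis_fill,fao_fra,globcover,mcd12q1
1,Brunei,5,0,4,3,5
2,Myanmar,343,0,318,235,359
3,Cambodia,70,0,101,56,55
4,East Timor,7,0,7,1,2
5,Indonesia,885,419,944,860,1396
6,Laos,148,0,158,112,184
7,Malaysia,222,0,205,180,274
8,Philippines,140,0,77,82,153
9,Singapore,0,0,0,0,0
10,Vietnam,128,0,138,111,131
11,Thailand,190,0,190,93,128
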