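country,days_insomnia,days_depression,days_suicide,deaths_increase,deaths_cum_mar20,cases_increase,cases_cum_mar20
Australia,5,6,0,60,7,5819,791
Brazil,10,0,0,2451,11,37861,793
Canada,4,4,1,1552,12,34676,943
France,9,0,2,19244,450,139196,12612
Germany,4,0,10,4519,67,125336,19848
Hong Kong,1,6,3,0,4,769,256
Iran,17,9,10,3685,1433,62567,19644
Italy,11,1,5,19628,4032,131951,47021
Japan,1,0,0,203,33,9834,963
New Zealand,2,1,1,12,0,1392,39
Russia,1,0,0,360,1,42600,253
Singapore,3,0,2,11,0,6203,385
South Korea,1,3,2,140,94,2009,8652
Spain,16,4,0,19410,1043,178264,20410
Taiwan,4,2,4,4,2,285,135
Thailand,6,2,1,46,1,2443,322
Turkey,2,0,0,2013,4,85947,359
United Kingdom,4,0,0,18298,194,116084,3983
United States,11,4,1,40596,349,739536,19273
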