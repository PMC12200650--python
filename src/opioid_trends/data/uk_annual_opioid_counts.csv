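year,n_registered,n_incident,n_ltot,n_discontinuers,rate_incident,rate_ltot,rate_discontinuers
2009,1165440,254066,31905,1690,21.80,12.56,5.30
2010,1194284,262411,31978,1620,21.97,12.19,5.07
2011,1218921,266417,32001,1589,21.86,12.01,4.97
2012,1240969,274116,31515,1570,22.09,11.50,4.98
2013,1260446,275520,31261,1569,21.86,11.35,5.02
2014,1358015,280519,31749,1470,20.66,11.32,4.63
2015,1326781,278251,30480,1416,20.97,10.95,4.65
2016,1328107,269706,29697,1391,20.31,11.01,4.68
2017,1332717,249669,27646,1237,18.73,11.07,4.47
2018,1323147,224008,24424,1057,16.93,10.90,4.33
2019,1392118,204478,22221,875,14.69,10.87,3.94
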