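variety,release_year,wheat_type,mean_yield_kg_ha,sd_yield_kg_ha,cv_pct,n_obs,pct_irrigated
TUGELA-DN,1992,winter,3123,1748.23,55.97,416,0
BETTADN,1993,winter,2632,1299.82,49.38,2070,0.39
GARIEP,1994,facultative,2818,1346.40,47.78,2420,0.33
LIMPOPO,1994,facultative,2679,1357,50.66,2055,0.39
KARIEGA,1994,spring,5598,2274.98,40.64,3733,66.33
MARICO,1994,spring,6338,2110.16,33.29,1510,99.27
CALEDON,1996,facultative,2780,1298.22,46.7,2176,0.37
ELANDS,1999,facultative,2873,1367.65,47.6,2407,0.33
STEENBRAS,2000,spring,6102,1956.85,32.07,2273,96.48
BAVIAANS,2001,spring,5527,2202.30,39.85,3305,67.08
KOMATI,2003,facultative,2762,1371.96,49.67,1519,0.53
BIEDOU,2003,spring,4671,1946.57,41.67,763,48.23
OLIFANTS,2003,spring,6565,2000.29,30.47,1948,98.56
TARKA,2003,winter,2188,1081.85,49.44,262,3.05
DUZI,2006,spring,6772,2072.59,30.61,1893,94.51
KROKODIL,2006,spring,7059,2184.77,30.95,1793,100
MATLABAS,2006,winter,3061,1518.48,49.6,1258,0
NOSSOB,2006,winter,1732,957.7,55.28,281,0
BUFFELS,2009,spring,7276,2155.46,29.62,833,100
TANKWA,2009,spring,3682,1170.38,31.79,841,0
SABIE,2010,spring,7475,2015.39,26.96,843,98.1
KOONAP,2012,spring,2604,1241.29,47.67,358,0
KWARTEL,2012,spring,3715,989.87,26.65,434,0
RATEL,2012,spring,4016,1081.63,26.94,431,0
SENQU,2012,spring,2891,1398.66,48.39,235,0
UMLAZI,2012,spring,8021,1837.05,22.9,450,100
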