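year,area_spring_irrigated_ha,area_winter_ha,area_facultative_ha,price_usd_per_ton,price_2016usd_per_ton
1992,334813,6631,8066,250.00,428.88
1993,368953,20612,200382,230.40,382.12
1994,420263,22218,148430,212.60,344.52
1995,400307,56428,238609,218.60,344.58
1996,321059,35062,307282,210.50,323.00
1997,181780,37713,229113,177.50,264.32
1998,27226,20091,149071,146.20,215.27
1999,42564,9765,22723,157.30,226.61
2000,10118,2148,6779,167.90,234.01
2001,29661,15097,35954,165.20,223.88
2002,18065,15714,42731,149.10,198.92
2003,21086,1122,27994,188.80,246.27
2004,30133,2158,41746,168.90,214.60
2005,38185,6833,91607,162.60,199.82
2006,83712,5776,33099,225.10,267.98
2007,62719,13678,11808,355.70,411.74
2008,60867,11203,49421,279.30,311.35
2009,74963,3010,15900,189.80,212.33
2010,44187,3845,37396,316.10,347.92
2011,61520,2781,12310,326.40,348.26
2012,40124,2149,5482,354.90,371.00
2013,23703,1499,1652,298.30,307.33
2014,8231,1541,844,281.30,285.19
2015,930,2457,2448,295.20,298.92
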