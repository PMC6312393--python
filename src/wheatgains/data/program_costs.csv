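year,cost_2016usd
1992,1204967
1993,1157053
1994,1107952
1995,1055208
1996,1031498
1997,982730
1998,981071
1999,935746
2000,941295
2001,909867
2002,894494
2003,827780
2004,756428
2005,820042
2006,844848
2007,841515
2008,863566
2009,848179
2010,690641
2011,689671
2012,605516
2013,600437
2014,658406
2015,634556
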