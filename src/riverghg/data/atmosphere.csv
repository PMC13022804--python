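year,xCO2_ppm,xCH4_ppm,xN2O_ppb
2000,368.84,1.7732,315.8
2001,370.41,1.7712,316.4
2002,372.42,1.7726,316.9
2003,375.00,1.7773,317.6
2004,376.78,1.7770,318.3
2005,378.81,1.7741,319.3
2006,380.93,1.7747,320.1
2007,382.67,1.7812,320.9
2008,384.78,1.7869,321.8
2009,386.28,1.7935,322.4
2010,388.56,1.7989,323.3
2011,390.44,1.8030,324.3
2012,392.45,1.8080,325.0
2013,395.19,1.8133,325.9
2014,397.11,1.8225,327.1
2015,399.41,1.8341,328.2
2016,402.85,1.8430,328.9
2017,404.98,1.8496,329.7
2018,407.38,1.8573,330.9
2019,409.85,1.8666,331.9
2020,412.44,1.8789,333.0
2021,414.70,1.8953,334.3
2022,417.07,1.9118,335.7
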