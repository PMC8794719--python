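year,rate_name,age_class,mean,se,n
2013,NI1,SY,1.00,0.00,6
2013,NI1,ASY,0.94,0.003,16
2013,NI2,pooled,0.20,0.01,15
2013,CS1,SY,6.26,0.75,4
2013,CS1,ASY,6.33,0.31,7
2013,CS2,ASY,4.64,0.30,1
2013,H,pooled,0.95,0.001,59
2013,NS1,SY,0.55,0.12,6
2013,NS1,ASY,0.19,0.12,15
2013,NS2,pooled,0.17,0.21,3
2013,S_chick,pooled,0.21,0.08,5
2013,S_juv,pooled,0.34,0.07,30
2013,S_breed,SY,0.47,0.09,16
2013,S_breed,ASY,0.55,0.07,30
2013,S_fall,SY,0.48,0.09,16
2013,S_fall,ASY,0.55,0.07,30
2013,S_winter,SY,0.67,0.09,16
2013,S_winter,ASY,0.72,0.07,30
2013,S_annual,SY,0.20,0.07,16
2013,S_annual,ASY,0.27,0.07,30
2014,NI1,SY,1.00,0.00,9
2014,NI1,ASY,1.00,0.00,14
2014,NI2,pooled,0.52,0.01,23
2014,CS1,SY,6.00,0.84,5
2014,CS1,ASY,7.00,0.42,8
2014,CS2,SY,4.61,0.40,1
2014,CS2,ASY,5.31,0.30,5
2014,H,pooled,0.95,0.001,59
2014,NS1,SY,0.49,0.14,8
2014,NS1,ASY,0.23,0.11,12
2014,NS2,pooled,0.65,0.19,7
2014,S_chick,pooled,0.24,0.10,9
2014,S_juv,pooled,0.56,0.07,14
2014,S_breed,SY,0.64,0.09,8
2014,S_breed,ASY,0.70,0.08,14
2014,S_fall,SY,0.64,0.09,8
2014,S_fall,ASY,0.70,0.08,14
2014,S_winter,SY,0.79,0.08,8
2014,S_winter,ASY,0.83,0.06,14
2014,S_annual,SY,0.37,0.11,8
2014,S_annual,ASY,0.45,0.11,14
2015,NI1,SY,0.82,0.01,11
2015,NI1,ASY,1.00,0.00,16
2015,NI2,pooled,0.25,0.01,16
2015,CS1,SY,6.40,0.51,5
2015,CS1,ASY,7.13,0.39,8
2015,CS2,ASY,5.44,0.30,1
2015,H,pooled,0.95,0.001,59
2015,NS1,SY,0.57,0.12,9
2015,NS1,ASY,0.37,0.12,15
2015,NS2,pooled,0.43,0.25,4
2015,S_chick,pooled,0.38,0.06,12
2015,S_juv,pooled,0.94,0.07,17
2015,S_breed,SY,0.83,0.06,13
2015,S_breed,ASY,0.87,0.05,17
2015,S_fall,SY,0.84,0.06,13
2015,S_fall,ASY,0.87,0.05,17
2015,S_winter,SY,0.91,0.04,13
2015,S_winter,ASY,0.93,0.03,17
2015,S_annual,SY,0.68,0.11,13
2015,S_annual,ASY,0.75,0.09,17
2016,NI1,SY,1.00,0.00,3
2016,NI1,ASY,0.87,0.004,31
2016,NI2,pooled,0.15,0.01,26
2016,CS1,SY,4.67,0.66,3
2016,CS1,ASY,6.05,0.43,20
2016,CS2,ASY,4.36,0.30,2
2016,H,pooled,0.95,0.001,59
2016,NS1,SY,0.50,0.15,3
2016,NS1,ASY,0.29,0.07,27
2016,NS2,pooled,0.23,0.21,4
2016,S_chick,pooled,0.33,0.08,8
2016,S_juv,pooled,0.76,0.07,35
2016,S_breed,SY,0.75,0.07,13
2016,S_breed,ASY,0.77,0.05,35
2016,S_fall,SY,0.75,0.06,13
2016,S_fall,ASY,0.80,0.05,35
2016,S_winter,SY,0.86,0.05,13
2016,S_winter,ASY,0.89,0.04,35
2016,S_annual,SY,0.53,0.10,13
2016,S_annual,ASY,0.61,0.08,35
2017,NI1,SY,0.90,0.01,10
2017,NI1,ASY,1.00,0.00,20
2017,NI2,pooled,0.59,0.01,17
2017,CS1,SY,5.06,0.79,6
2017,CS1,ASY,6.23,0.31,15
2017,CS2,SY,3.67,0.40,3
2017,CS2,ASY,4.54,0.30,7
2017,H,pooled,0.95,0.001,59
2017,NS1,SY,0.53,0.10,8
2017,NS1,ASY,0.42,0.13,19
2017,NS2,pooled,0.65,0.17,11
2017,S_chick,pooled,0.25,0.06,19
2017,S_juv,pooled,0.73,0.07,27
2017,S_breed,SY,0.73,0.07,17
2017,S_breed,ASY,0.77,0.05,27
2017,S_fall,SY,0.73,0.07,17
2017,S_fall,ASY,0.78,0.05,27
2017,S_winter,SY,0.84,0.05,17
2017,S_winter,ASY,0.87,0.04,27
2017,S_annual,SY,0.50,0.10,17
2017,S_annual,ASY,0.58,0.08,27
2018,NI1,SY,0.78,0.02,9
2018,NI1,ASY,1.00,0.00,19
2018,NI2,pooled,0.36,0.02,14
2018,CS1,SY,7.17,0.40,6
2018,CS1,ASY,7.07,0.38,15
2018,CS2,ASY,5.38,0.30,2
2018,H,pooled,0.95,0.001,59
2018,NS1,SY,0.58,0.14,5
2018,NS1,ASY,0.36,0.10,18
2018,NS2,pooled,0.20,0.21,3
2018,S_chick,pooled,0.18,0.05,10
2018,S_juv,pooled,0.68,0.07,23
2018,S_breed,SY,0.70,0.06,6
2018,S_breed,ASY,0.76,0.06,23
2018,S_fall,SY,0.71,0.08,6
2018,S_fall,ASY,0.76,0.06,23
2018,S_winter,SY,0.83,0.07,6
2018,S_winter,ASY,0.86,0.05,23
2018,S_annual,SY,0.46,0.10,6
2018,S_annual,ASY,0.54,0.12,23
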