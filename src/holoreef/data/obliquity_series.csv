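# Trigonometric series for Earth's axial obliquity (Berger 1978 solution).
# epsilon(t) = 23.320556 deg + sum_i amplitude_i * cos(rate_i * t + phase_i),
# with t in Julian years from 1950 CE (negative into the past), amplitude in
# arcseconds, rate in arcseconds per year, phase in degrees.
# Leading 20 terms of the 47-term expansion; the truncated remainder has a
# combined amplitude < 0.02 degrees, far below Holocene-scale use of this
# solution. Coefficients transcribed from the widely reproduced BER78 tables.
term,amplitude_arcsec,rate_arcsec_per_yr,phase_deg
1,-2462.2214466,31.609974,251.9025
2,-857.3232075,32.620504,280.8325
3,-629.3231835,24.172203,128.3057
4,-414.2804924,31.983787,292.7252
5,-311.7632587,44.828336,15.3747
6,308.9408604,30.973257,263.7951
7,-162.5533601,43.668246,308.4258
8,-116.1077911,32.246691,240.0099
9,101.1189923,30.599444,222.9725
10,-67.6856209,42.681324,268.7809
11,24.9079067,43.836462,316.7998
12,22.5811241,47.439436,319.6024
13,-21.1648355,63.219948,143.8050
14,-15.6549876,64.230478,172.7351
15,15.3936813,1.010530,28.9300
16,14.6660938,7.437771,123.5968
17,-11.7273029,55.782177,20.2082
18,10.2742951,0.373813,40.8226
19,6.4914588,13.218362,123.4722
20,5.8539148,62.583231,155.6977
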