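# Trigonometric series for the eccentricity / fixed-equinox perihelion vector
# (Berger 1978 solution).  With t in Julian years from 1950 CE (negative into
# the past), rate in arcseconds per year and phase in degrees:
#   e*sin(Pi) = sum_i amplitude_i * sin(rate_i * t + phase_i)
#   e*cos(Pi) = sum_i amplitude_i * cos(rate_i * t + phase_i)
# where Pi is the longitude of perihelion measured from the fixed vernal
# equinox of 1950.  Eccentricity is the modulus of the vector.  All 19 terms
# of the expansion.  Coefficients transcribed from the widely reproduced
# BER78 tables.
term,amplitude,rate_arcsec_per_yr,phase_deg
1,0.01860798,4.2072050,28.620089
2,0.01627522,7.3460910,193.788772
3,-0.01300660,17.8572630,308.307024
4,0.00988829,17.2205460,320.199637
5,-0.00336700,16.8467330,279.376984
6,0.00333077,5.1990790,87.195000
7,-0.00235400,18.2310760,349.129677
8,0.00140015,26.2167580,128.443387
9,0.00100700,6.3591690,154.143880
10,0.00085700,16.2100160,291.269597
11,0.00064990,3.0651810,114.860583
12,0.00059900,16.5838290,332.092251
13,0.00037800,18.4939800,296.414411
14,-0.00033700,6.1909530,145.769910
15,0.00027600,18.8677930,337.237063
16,0.00018200,17.4255670,152.092288
17,-0.00017400,6.1860010,126.839891
18,-0.00012400,18.4174410,210.667199
19,0.00001250,0.6678630,72.108838
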