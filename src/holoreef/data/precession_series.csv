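# Periodic terms of the general precession in longitude (Berger 1978
# solution).  With t in Julian years from 1950 CE (negative into the past):
#   psi(t) = psi_bar * t + zeta + sum_i amplitude_i * sin(rate_i * t + phase_i)
# where psi_bar = 50.439273 arcsec/yr, zeta = 3.392506 deg, amplitude in
# arcseconds, rate in arcseconds per year, phase in degrees.  Leading 10 terms
# of the 78-term expansion; the truncation error in the longitude of
# perihelion is ~1 degree, i.e. < 0.0005 in the climatic precession index.
# Coefficients transcribed from the widely reproduced BER78 tables.
term,amplitude_arcsec,rate_arcsec_per_yr,phase_deg
1,7391.0225890,31.609974,251.9025
2,2555.1526947,32.620504,280.8325
3,2022.7629188,24.172203,128.3057
4,-1973.6517951,0.636717,348.1074
5,1240.2321818,31.983787,292.7252
6,953.8679112,3.138886,165.1686
7,-931.7537108,30.973257,263.7951
8,872.3795383,44.828336,15.3747
9,606.3544732,0.991874,58.5749
10,-496.0274038,0.373813,40.8226
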