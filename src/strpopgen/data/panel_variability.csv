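locus,pooled_He,mean_He_per_population,n_alleles,mean_alleles_per_population,repeat_dispersion,mean_dispersion_per_population
D3S1358,0.77543,0.76634,8,5.647,7,4.765
TH01,0.78141,0.76693,8,5.588,6,3.588
D21S11,0.84974,0.84229,17,10.588,9,6.353
D18S51,0.87419,0.86735,18,11.882,16,11.118
PentaE,0.91497,0.90474,18,15.176,18,16.118
D5S818,0.73859,0.73546,9,6.529,8,5.941
D13S317,0.79676,0.78925,10,7.176,9,6.176
D7S820,0.80174,0.79478,12,7.471,10,6.471
D16S539,0.78966,0.78064,9,7.000,7,5.941
CSF1PO,0.73503,0.73035,8,5.882,7,5.059
PentaD,0.82446,0.82034,13,8.588,17,8.588
vWA,0.79355,0.79053,10,7.176,9,6.235
D8S1179,0.79676,0.79044,11,8.471,10,7.647
TPOX,0.61227,0.60398,8,5.294,7,4.412
FGA,0.85811,0.85062,20,10.941,13,8.882
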