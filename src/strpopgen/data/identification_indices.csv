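population,MP_total,reciprocal_printed,PE_total,PI_total
Belgorod,1.66e-16,6.33e15,0.999998,742717
Orel,2.53e-16,3.95e15,0.9999992,1003109
Orenburg,1.06e-16,9.36e15,0.9999991,1065170
Yaroslavl,2.46e-16,4.04e15,0.9999997,3378695
Tomsk,3.44e-18,2.81e17,0.9999990,880293
Russians_total,3.19e-18,3.12e17,0.9999989,834233
Belorussians,9.11e-17,1.08e16,0.999997,284297
Ukrainians,6.34e-18,1.56e17,0.9999995,1834277
Komi,5.60e-17,1.73e16,0.999998,451441
Mari,3.28e-16,3.04e15,0.99998,46918
Khakas,7.42e-17,1.37e16,0.99991,192783
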