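locus,Belgorod,Orel,Orenburg,Yaroslavl,Belorussians,Ukrainians,Komi,Mari,Tomsk,Khakas,Moscow,Dargins,Lezgins,Avars,Bashkir,Tatar,Chuvash
D3S1358,0.79434,0.77946,0.77232,0.75394,0.73459,0.79831,0.76929,0.78771,0.78909,0.68603,0.79342,0.77325,0.79535,0.77616,0.72816,0.72917,0.76712
TH01,0.76465,0.76024,0.78586,0.76707,0.78094,0.77249,0.74990,0.72087,0.78202,0.74157,0.75644,0.79518,0.74040,0.78384,0.78479,0.77686,0.77466
D21S11,0.83960,0.83460,0.85556,0.86465,0.86742,0.86777,0.85354,0.84055,0.85443,0.81528,0.85224,0.83224,0.86465,0.82020,0.79486,0.81222,0.84906
D18S51,0.87859,0.86469,0.87859,0.87071,0.86359,0.86551,0.87091,0.84839,0.87784,0.81938,0.88683,0.87149,0.86101,0.87273,0.86608,0.87847,0.87008
PentaE,0.90626,0.90390,0.90081,0.89778,0.89489,0.89926,0.90586,0.90497,0.91035,0.93258,0.90168,0.90548,0.91172,0.84869,0.92415,0.91695,0.91518
D5S818,0.73737,0.72898,0.73172,0.74404,0.74439,0.72419,0.73980,0.75243,0.75267,0.75956,0.71346,0.75022,0.76283,0.74465,0.69681,0.70383,0.71590
D13S317,0.76808,0.79616,0.80889,0.79434,0.81510,0.78100,0.78828,0.80284,0.80313,0.81332,0.77184,0.69825,0.77354,0.79960,0.79589,0.82834,0.77862
D7S820,0.81657,0.77985,0.75838,0.78101,0.78882,0.80208,0.80727,0.77072,0.80964,0.80928,0.79636,0.79232,0.81071,0.77273,0.81470,0.79230,0.80845
D16S539,0.70889,0.76471,0.76626,0.77455,0.77520,0.75109,0.76485,0.77857,0.76974,0.79615,0.77691,0.82456,0.79091,0.80444,0.81048,0.80734,0.80629
CSF1PO,0.73838,0.70938,0.75636,0.72970,0.73865,0.74740,0.76141,0.70874,0.73273,0.74584,0.71527,0.69737,0.67495,0.73172,0.72528,0.76440,0.73836
PentaD,0.82202,0.82392,0.81111,0.80869,0.83516,0.82482,0.81192,0.79593,0.83174,0.81682,0.81597,0.80855,0.85010,0.80000,0.82713,0.84677,0.81509
vWA,0.81212,0.77888,0.81960,0.80909,0.79312,0.80398,0.81818,0.76176,0.77623,0.76734,0.81653,0.75504,0.82525,0.81111,0.76053,0.75559,0.77466
D8S1179,0.74889,0.80606,0.79919,0.81899,0.80029,0.79702,0.81333,0.74571,0.79657,0.74964,0.79566,0.79298,0.79333,0.76545,0.81357,0.81358,0.78724
TPOX,0.64646,0.54533,0.61818,0.59879,0.55638,0.63578,0.60061,0.52502,0.62928,0.61469,0.59608,0.65175,0.74727,0.57354,0.60113,0.58231,0.54501
FGA,0.86586,0.81965,0.85131,0.85778,0.86168,0.85447,0.85960,0.82207,0.85388,0.83904,0.87171,0.80899,0.84909,0.84727,0.86701,0.87170,0.85948
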