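scenario,BSD,BBOEL,DA,GWO,UEO,NVSA
CT vs. PD (P001),30.983,30.928,31.046,33.930,30.342,29.865
CT vs. T1 (P001),32.150,31.392,32.108,32.415,31.319,30.647
CT vs. T2 (P001),33.139,33.554,34.376,33.930,33.706,34.221
CT vs. PD (P002),34.544,34.736,34.135,33.910,34.356,35.075
CT vs. T1 (P002),33.907,35.141,33.607,33.775,33.516,34.021
CT vs. T2 (P002),32.373,34.105,32.761,35.361,34.140,35.927
CT vs. T1 (P003),27.480,27.055,27.239,28.038,27.336,26.974
CT vs. T2 (P003),26.286,28.020,26.452,26.429,25.864,26.155
CT vs. PD (P004),26.313,26.109,26.496,27.411,25.596,25.439
CT vs. T1 (P004),29.977,29.405,29.784,31.764,29.289,28.494
CT vs. T2 (P004),30.996,30.879,30.470,31.249,30.748,31.006
CT vs. PD (P005),35.831,35.703,35.814,35.485,35.488,34.870
CT vs. T1 (P005),37.034,36.611,36.538,36.204,36.603,36.381
CT vs. T2 (P005),30.996,30.879,31.596,32.792,33.186,31.006
CT vs. PD (P006),27.771,26.903,27.086,27.274,26.627,26.356
CT vs. T1 (P006),30.771,29.755,29.881,30.345,29.801,29.029
CT vs. T2 (P006),36.231,37.747,35.695,35.873,36.331,37.080
CT vs. PD (P007),29.371,29.866,29.801,29.245,29.421,30.115
CT vs. T1 (P007),30.188,30.186,30.243,30.030,30.044,29.809
CT vs. T2 (P007),30.308,31.189,30.037,30.595,31.270,33.133
CT vs. PD (P101),59.960,64.670,62.386,61.076,60.300,60.137
CT vs. T1 (P101),53.532,54.813,55.161,53.528,52.369,52.361
CT vs. T2 (P101),60.317,63.726,64.632,65.427,62.433,61.956
CT vs. PD (P102),49.270,53.669,51.798,48.811,49.055,49.677
CT vs. T1 (P102),52.005,57.916,52.811,50.681,50.493,51.358
CT vs. T2 (P102),63.452,57.181,67.361,66.000,64.874,64.423
CT vs. PD (P103),36.034,57.019,37.617,34.821,35.250,35.211
CT vs. T1 (P103),40.342,50.678,41.175,41.321,39.941,38.891
CT vs. PD (P104),43.984,44.878,48.248,42.938,45.058,45.882
CT vs. T1 (P104),49.713,48.358,50.353,46.894,48.776,49.548
CT vs. T2 (P104),53.832,54.370,55.708,55.994,53.918,54.434
CT vs. T1 (P105),47.850,46.734,48.626,47.088,47.584,47.291
CT vs. T2 (P105),51.845,53.674,55.673,54.409,52.756,52.053
CT vs. T1 (P106),53.165,61.415,53.742,51.176,51.369,51.181
CT vs. T2 (P106),60.899,61.679,64.310,64.673,62.950,62.300
CT vs. T1 (P107),49.387,54.494,49.628,50.285,49.977,50.188
CT vs. T2 (P107),51.916,54.696,55.058,58.583,53.218,47.755
CT vs. T1 (P108),47.089,50.464,48.054,46.269,45.817,45.895
CT vs. T2 (P108),53.965,55.935,55.958,56.407,55.367,55.332
CT vs. T1 (P109),49.716,55.211,52.836,51.730,49.663,48.678
CT vs. T2 (P109),59.365,59.065,61.643,59.027,59.838,58.017
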