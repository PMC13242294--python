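method,151507,151508,151509,151510,151669,151670,151671,151672,151673,151674,151675,151676
conST,0.260,0.370,0.420,0.330,0.300,0.230,0.380,0.380,0.510,0.450,0.440,0.390
DeepST,0.530,0.440,0.490,0.460,0.330,0.330,0.490,0.500,0.590,0.430,0.520,0.490
SpaceFlow,0.310,0.260,0.210,0.210,0.200,0.170,0.260,0.280,0.350,0.340,0.250,0.290
STAGATE,0.590,0.430,0.430,0.430,0.390,0.510,0.300,0.540,0.510,0.540,0.570,0.510
SpaGCN,0.430,0.380,0.370,0.400,0.300,0.210,0.380,0.510,0.480,0.410,0.390,0.320
GraphST,0.430,0.490,0.420,0.510,0.430,0.380,0.600,0.610,0.630,0.430,0.480,0.570
Scatter,0.471,0.397,0.481,0.384,0.395,0.377,0.468,0.734,0.661,0.546,0.457,0.425
ACT,0.486,0.336,0.484,0.350,0.372,0.386,0.621,0.582,0.661,0.580,0.322,0.369
FACT,0.554,0.313,0.514,0.441,0.392,0.407,0.635,0.605,0.668,0.467,0.253,0.259
Ensemble (ASW),0.590,0.490,0.430,0.441,0.395,0.407,0.635,0.582,0.661,0.580,0.480,0.510
Ensemble (PAS),0.554,0.490,0.514,0.510,0.395,0.407,0.621,0.582,0.661,0.467,0.457,0.369
Ensemble (CHAOS),0.554,0.336,0.430,0.350,0.395,0.510,0.621,0.582,0.630,0.580,0.480,0.510
Ensemble,0.590,0.490,0.481,0.510,0.395,0.510,0.468,0.605,0.668,0.430,0.570,0.425
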