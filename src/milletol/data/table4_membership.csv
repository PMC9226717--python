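variety,MDA,soluble_protein,chlorophyll,net_photosynthetic_rate,transpiration_rate,stomatal_conductance,dry_matter,grain_weight_per_panicle,T_printed,rank_printed
JG26,0.99,0.35,0.75,0.72,0.26,0.28,0.88,0.85,0.59,7
FX3,0.67,0.19,0.99,1.00,1.00,0.91,0.95,0.73,0.80,2
ZGG,0.21,0.06,0.46,0.34,0.31,0.35,0.34,0.48,0.31,16
JG40,0.67,0.37,0.35,0.13,0.18,0.41,0.23,0.49,0.30,17
DBG,0.00,0.53,0.87,0.58,0.59,0.47,0.56,0.52,0.52,10
GA2,0.99,0.58,0.99,0.99,0.99,1.00,0.92,0.84,0.91,1
SDLS,0.89,0.30,0.89,0.62,0.73,0.90,0.86,0.78,0.74,4
SXWG,0.17,0.80,0.39,0.65,0.46,0.82,0.70,0.00,0.54,9
HBXG,0.05,0.59,0.52,0.79,0.94,0.51,0.78,0.56,0.62,5
CG,0.66,0.43,0.80,0.95,0.70,1.02,1.00,0.85,0.80,3
NX15,0.28,0.61,0.13,0.45,0.11,0.25,0.00,1.00,0.32,14
LG25,0.31,0.00,0.20,0.17,0.52,0.35,0.04,0.54,0.26,19
ZTB,0.48,1.00,0.17,0.20,0.72,0.78,0.34,0.78,0.59,6
JSHJ,0.34,0.22,0.06,0.63,0.43,0.28,0.09,0.53,0.31,15
LG31,0.15,0.08,0.00,0.00,0.00,0.07,0.16,0.30,0.09,20
HJDG,0.77,0.23,0.63,0.86,0.40,0.90,0.37,0.35,0.56,8
GA5,0.29,0.49,0.60,0.69,0.57,0.37,0.29,0.36,0.45,12
YG2,0.19,0.16,0.88,0.83,0.22,0.74,0.54,0.74,0.52,11
ZGB,0.51,0.16,0.13,0.65,0.42,0.46,0.45,0.80,0.43,13
BGHNG,0.27,0.28,0.60,0.12,0.20,0.00,0.42,0.43,0.27,18
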