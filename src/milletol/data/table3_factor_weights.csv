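indicator,PC1,PC2,PC3,weight
MDA,0.605,-0.382,0.433,0.10
soluble_protein,0.157,0.814,0.471,0.14
chlorophyll,0.817,-0.126,-0.299,0.10
net_photosynthetic_rate,0.803,-0.070,-0.303,0.10
transpiration_rate,0.752,0.348,-0.046,0.15
stomatal_conductance,0.832,0.220,0.059,0.16
dry_matter,0.880,0.009,-0.161,0.15
grain_weight_per_panicle,0.440,-0.430,0.634,0.09
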