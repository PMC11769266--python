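# Endmember reflectance spectra for the two-endmember canopy mixing model and
# the bare-soil background, on the five sensor bands (blue, green, red,
# red-edge, NIR).  Chosen so that canopy and soil NDVIre populations are
# bimodal (soil ~0.11, canopy 0.42-0.80) and the registry indices span
# realistic ranges for a smectitic clay field.

[healthy_canopy]
blue = 0.030
green = 0.080
red = 0.040
rededge = 0.350
nir = 0.550

[stressed_canopy]
blue = 0.050
green = 0.100
red = 0.090
rededge = 0.220
nir = 0.300

[bare_soil]
blue = 0.080
green = 0.120
red = 0.160
rededge = 0.200
nir = 0.240
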