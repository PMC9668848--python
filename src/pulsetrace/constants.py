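"""Physical and study constants used throughout the package.

Isotope reference ratios are the conventional values for VPDB (13C/12C) and
atmospheric N2 (15N/14N).  Conversion factors, chamber geometry and sampling
depth are the values the field protocol fixes; every one of them can be
overridden per run through :class:`pulsetrace.pipeline.RunConfig`.
"""

# Heavy/light isotope ratios of the international reference materials.
R_VPDB = 0.0111802   # 13C/12C of Vienna Pee Dee Belemnite
R_AIR = 0.0036765    # 15N/14N of atmospheric N2

#: delta 13C of the methanol used in FAME derivatization (permil vs VPDB)
METHANOL_D13C = -29.3

#: nmol of the fungal biomarker PLFA 18:2w6,9 equivalent to 1 mg fungal C
FUNGAL_PLFA_PER_MG_C = 11.8
#: nmol of summed bacterial biomarker PLFA equivalent to 1 mg bacterial C
BACTERIAL_PLFA_PER_MG_C = 363.6

# Static-chamber geometry and ambient defaults
CHAMBER_VOLUME_L = 1.2
GAS_COLLAR_DIAMETER_CM = 11.0
DEFAULT_TEMPERATURE_K = 293.15
DEFAULT_PRESSURE_KPA = 101.325
R_GAS = 8.314  # J mol-1 K-1

# Subplot (isotope-labelling collar) geometry and soil sampling
SUBPLOT_COLLAR_DIAMETER_CM = 40.0
SOIL_DEPTH_CM = 7.0
DEFAULT_BULK_DENSITY_G_CM3 = 0.8

# 15N pulse: dose equivalent to 20 kg N per hectare at 98 atom % 15N
N15_DOSE_G_N_PER_M2 = 2.0
N15_TRACER_ATOM_PERCENT = 98.0

import math as _math

#: subplot area in m2 (40 cm diameter collar)
SUBPLOT_AREA_M2 = _math.pi * (SUBPLOT_COLLAR_DIAMETER_CM / 200.0) ** 2
#: gas collar area in m2 (11 cm diameter)
GAS_COLLAR_AREA_M2 = _math.pi * (GAS_COLLAR_DIAMETER_CM / 200.0) ** 2
#: grams of dry soil under one m2 at default bulk density and 7 cm depth
SOIL_MASS_G_PER_M2 = DEFAULT_BULK_DENSITY_G_CM3 * SOIL_DEPTH_CM * 1e4
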