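"""Controlled vocabularies and published parameter tables.

Land-use classes follow the habitat table of the Chinese national
eco-environment assessment standard (HJ 192-2015): six top-level classes,
each with habitat subtypes.  Subtype codes are two-digit integers whose tens
digit is the parent land-use code, so ``subtype // 10`` recovers the class.
"""

from __future__ import annotations

# --- land use / habitat -----------------------------------------------------

WOODLAND = 1
GRASSLAND = 2
WATER_WETLAND = 3
ARABLE_LAND = 4
CONSTRUCTION_LAND = 5
UNUTILIZED_LAND = 6

LANDUSE_NAMES = {
    WOODLAND: "woodland",
    GRASSLAND: "grassland",
    WATER_WETLAND: "water_wetland",
    ARABLE_LAND: "arable_land",
    CONSTRUCTION_LAND: "construction_land",
    UNUTILIZED_LAND: "unutilized_land",
}
LANDUSE_CODES = {v: k for k, v in LANDUSE_NAMES.items()}

HABITAT_NAMES = {
    11: "woodland",
    12: "shrubbery",
    13: "sparse_woodland",
    21: "high_coverage_grass",
    22: "medium_coverage_grass",
    23: "low_coverage_grass",
    31: "river",
    32: "lake",
    33: "beach_wetland",
    34: "permanent_glacier_snow",
    41: "paddy_field",
    42: "rainfed_cropland",
    51: "urban_construction_land",
    52: "rural_settlement",
    53: "other_construction_land",
    61: "sandy_land",
    62: "saline_alkali_land",
    63: "bare_land",
    64: "bare_rock_gravel",
    65: "other_unused_land",
}
HABITAT_CODES = {v: k for k, v in HABITAT_NAMES.items()}

# Weight of each land-use class in the habitat-quality index, and the weight
# of each habitat subtype within its class.
LANDUSE_WEIGHTS = {
    WOODLAND: 0.35,
    GRASSLAND: 0.21,
    WATER_WETLAND: 0.28,
    ARABLE_LAND: 0.11,
    CONSTRUCTION_LAND: 0.04,
    UNUTILIZED_LAND: 0.01,
}
HABITAT_WEIGHTS = {
    11: 0.60, 12: 0.25, 13: 0.15,
    21: 0.60, 22: 0.30, 23: 0.10,
    31: 0.10, 32: 0.30, 33: 0.50, 34: 0.10,
    41: 0.60, 42: 0.40,
    51: 0.30, 52: 0.40, 53: 0.30,
    61: 0.20, 62: 0.30, 63: 0.20, 64: 0.20, 65: 0.10,
}

# --- EI composite weights ---------------------------------------------------

EI_WEIGHTS = {
    "biological_abundance": 0.35,
    "vegetation_coverage": 0.25,
    "river_density": 0.15,
    "land_stress": 0.15,
    "pollution_loading": 0.10,
}

# --- CASA light-use efficiency (gC per MJ) ----------------------------------
# Maximum LUE by vegetation type.  Sparse woodland and shrubbery are habitat
# subtypes of the woodland class but carry their own maxima; every other class
# uses the common 0.542 value.
EPS_MAX = {
    "woodland": 0.638,
    "shrubbery": 0.429,
    "sparse_woodland": 0.475,
    "grassland": 0.542,
    "water_wetland": 0.542,
    "construction_land": 0.542,
    "arable_land": 0.542,
    "unutilized_land": 0.542,
}

FPAR_MIN = 0.001
FPAR_MAX = 0.95

# --- river density / land stress normalization coefficients -----------------

A_RIV = 84.3704
A_LAK = 591.7909
A_RES = 86.387
A_ERO = 236.0436

EROSION_WEIGHTS = {"severe": 0.4, "other": 0.2, "none": 0.0}

# --- soils ------------------------------------------------------------------

SOIL_NEW = 1
SOIL_FLUVO_AQUIC = 2
SOIL_CINNAMON = 3
SOIL_LOESS = 4
SOIL_NAMES = {
    SOIL_NEW: "new",
    SOIL_FLUVO_AQUIC: "fluvo_aquic",
    SOIL_CINNAMON: "cinnamon",
    SOIL_LOESS: "loess",
}
ERODIBLE_SOILS = frozenset({SOIL_CINNAMON, SOIL_LOESS})

# --- mine feature vocabularies ----------------------------------------------

FEATURE_CLASSES = frozenset({
    "stope", "open_pit", "concentrator_plant", "ore_pile",
    "coal_pile", "dumping_site", "tailings_pond",
})
MINERALS = frozenset({"metal", "non_metal"})
METHODS = frozenset({"open_pit", "underground"})

# --- seasons (months, March-first study window) -----------------------------

SEASON_MONTHS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}
STUDY_MONTHS = (3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 1, 2)

# --- five-level classification ----------------------------------------------

CLASS_BREAKS = (0.2, 0.4, 0.6, 0.8)
CLASS_NAMES = {1: "very bad", 2: "bad", 3: "moderate", 4: "good", 5: "very good"}
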