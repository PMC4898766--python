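"""Reference data for the Núi Chúa National Park leaf-beetle survey.

Published summary data for the study site: georeferenced sampling
localities along six forest paths, per-path species richness under two
delimitation hypotheses, the printed path-by-path similarity matrix, and
the agreement accounting between DNA-based delimitations and
morphospecies.  These constants serve as worked-example inputs and as the
geometry template for the synthetic gradient-community generator.
"""

from __future__ import annotations

# Locality registry: (path, locality, latitude, longitude, elevation_m,
# n_specimens).  Six radial forest paths; DH lies ~8-10 km from the
# others and is conventionally excluded from community analyses.
LOCALITIES: list[tuple[str, str, float, float, float, int]] = [
    ("DH", "DH1", 11.6956389, 109.162736, 109, 11),
    ("DH", "DH2", 11.7021667, 109.148444, 233, 15),
    ("DH", "DH3", 11.7096528, 109.141736, 506, 2),
    ("DH", "DH4", 11.7156111, 109.136944, 661, 13),
    ("DH", "DH5", 11.7221667, 109.136111, 714, 9),
    ("AH", "AH1", 11.7279722, 109.202944, 50, 3),
    ("AH", "AH2", 11.7266389, 109.204750, 82, 6),
    ("AH", "AH3", 11.7310278, 109.209889, 142, 2),
    ("AH", "AH4", 11.7322222, 109.211278, 173, 2),
    ("AH", "AH5", 11.7352778, 109.212972, 200, 4),
    ("AH", "AH6", 11.7363889, 109.215111, 208, 6),
    ("AH", "AH7", 11.7358333, 109.216250, 236, 4),
    ("AH", "AH8", 11.7354444, 109.217264, 258, 7),
    ("AH", "AH9", 11.7349167, 109.218861, 260, 2),
    ("AH", "AH10", 11.7352222, 109.219500, 265, 2),
    ("DD", "DD1", 11.7226667, 109.181306, 111, 3),
    ("DD", "DD2", 11.7193889, 109.179361, 158, 3),
    ("DD", "DD3", 11.7177778, 109.178333, 188, 4),
    ("DD", "DD4", 11.7165556, 109.174611, 243, 3),
    ("DD", "DD5", 11.7145278, 109.175083, 230, 2),
    ("DD", "DD6", 11.7150556, 109.181528, 212, 4),
    ("DD", "DD1'", 11.7205833, 109.182944, 157, 2),
    ("DD", "DD2'", 11.7165694, 109.180903, 211, 2),
    ("DD", "DD3'", 11.7151944, 109.179236, 230, 4),
    ("DD", "DD4'", 11.7152222, 109.176625, 224, 2),
    ("DD", "DD5'", 11.7164167, 109.177278, 219, 3),
    ("MN", "MN1", 11.7279830, 109.189704, 38, 2),
    ("MN", "MN2", 11.7265833, 109.185528, 67, 10),
    ("MN", "MN3", 11.7246806, 109.182014, 107, 10),
    ("MN", "MN4", 11.7245556, 109.180417, 140, 4),
    ("MN", "MN5", 11.7246944, 109.179403, 166, 12),
    ("MN", "MN6", 11.7226944, 109.179417, 162, 2),
    ("MN", "MN7", 11.7251667, 109.177236, 180, 9),
    ("MN", "MN8", 11.7251806, 109.175125, 224, 15),
    ("MN", "MN9", 11.7238611, 109.174472, 244, 14),
    ("MN", "MN10", 11.7216528, 109.174681, 258, 9),
    ("MN", "MN11", 11.7207500, 109.173917, 269, 3),
    ("MN", "MN12", 11.7192361, 109.174944, 284, 15),
    ("MN", "MN13", 11.7182222, 109.172222, 324, 3),
    ("MN", "MN14", 11.7196667, 109.171222, 358, 3),
    ("MN", "MN15", 11.7192500, 109.170222, 364, 4),
    ("NO", "NO1", 11.7334444, 109.184389, 122, 15),
    ("NO", "NO2", 11.7341111, 109.182472, 174, 7),
    ("NO", "NO3", 11.7345556, 109.181222, 204, 5),
    ("NO", "NO4", 11.7349583, 109.180056, 238, 8),
    ("NO", "NO5", 11.7353889, 109.179111, 271, 3),
    ("NO", "NO6", 11.7356667, 109.177750, 340, 9),
    ("NO", "NO7", 11.7355000, 109.176889, 382, 11),
    ("NO", "NO8", 11.7362778, 109.175861, 411, 11),
    ("NO", "NO9", 11.7371667, 109.175958, 418, 6),
    ("NO", "NO10", 11.7379861, 109.175972, 428, 6),
    ("NO", "NO11", 11.7385556, 109.175861, 441, 9),
    ("NO", "NO12", 11.7402639, 109.175389, 486, 7),
    ("NO", "NO13", 11.7424444, 109.175250, 484, 4),
    ("NO", "NO14", 11.7456944, 109.175028, 474, 1),
    ("ST", "ST1", 11.7346667, 109.190583, 101, 4),
    ("ST", "ST2", 11.7368333, 109.190222, 171, 11),
    ("ST", "ST3", 11.7391667, 109.190653, 251, 11),
    ("ST", "ST4", 11.7411250, 109.191597, 287, 1),
    ("ST", "ST5", 11.7436528, 109.192681, 326, 21),
    ("ST", "ST6", 11.7446806, 109.192500, 351, 18),
    ("ST", "ST7", 11.7461667, 109.192167, 378, 13),
    ("ST", "ST8", 11.7485000, 109.192833, 405, 15),
    ("ST", "ST9", 11.7511528, 109.192319, 392, 18),
    ("ST", "ST10", 11.7534444, 109.192875, 376, 21),
]

PATH_NAMES = {
    "AH": "Ao Ho",
    "DD": "Da Do",
    "DH": "Da Hang",
    "MN": "Mai Nha",
    "NO": "Nui Ong",
    "ST": "Suoi Truc",
}

# Number of complete sampling rounds per path.
PATH_VISITS = {"AH": 4, "DD": 4, "DH": 1, "MN": 10, "NO": 10, "ST": 10}

# Observed species richness per data partition: morphospecies / DNA-based
# (bPTP) species.
PATH_RICHNESS = {
    "AH": (31, 32),
    "DD": (22, 23),
    "MN": (57, 59),
    "NO": (48, 52),
    "ST": (58, 61),
    "DH": (39, 40),
}
BIOME_RICHNESS = {"dry": (95, 103), "moist": (85, 90)}
TOTAL_RICHNESS = (140, 155)

BIOME_THRESHOLD_M = 300.0
ECOTONE_BAND_M = (160.0, 320.0)

# Published pairwise compositional similarity among the five community
# paths (DH excluded): Sørensen and Jaccard index per unordered pair.
SORENSEN_BY_PATH_PAIR = {
    ("AH", "DD"): 0.290,
    ("AH", "MN"): 0.329,
    ("AH", "NO"): 0.309,
    ("AH", "ST"): 0.322,
    ("DD", "MN"): 0.292,
    ("DD", "NO"): 0.240,
    ("DD", "ST"): 0.238,
    ("MN", "NO"): 0.378,
    ("MN", "ST"): 0.366,
    ("NO", "ST"): 0.460,
}
JACCARD_BY_PATH_PAIR = {
    ("AH", "DD"): 0.170,
    ("AH", "MN"): 0.197,
    ("AH", "NO"): 0.183,
    ("AH", "ST"): 0.192,
    ("DD", "MN"): 0.171,
    ("DD", "NO"): 0.136,
    ("DD", "ST"): 0.135,
    ("MN", "NO"): 0.233,
    ("MN", "ST"): 0.224,
    ("NO", "ST"): 0.298,
}

# Between-biome compositional similarity (dry vs moist compartments).
BIOME_SORENSEN = 0.42
BIOME_JACCARD = 0.27

# Agreement of each DNA-based delimitation with the 140 morphospecies:
# method -> (n_entities, agree, split, merge).
DELIMITATION_AGREEMENT = {
    "ML-r8s-single": (178, 122, 18, 0),
    "ML-r8s-multi": (186, 119, 21, 0),
    "ML-PATHd8-single": (160, 124, 16, 0),
    "ML-PATHd8-multi": (161, 39, 20, 81),
    "BI-strict-single": (162, 124, 16, 0),
    "BI-strict-multi": (165, 39, 21, 80),
    "BI-relaxed-single": (164, 122, 18, 0),
    "BI-relaxed-multi": (173, 119, 21, 0),
    "ML-bPTP": (155, 126, 14, 0),
}
N_MORPHOSPECIES = 140


def locality_points(exclude_paths: frozenset[str] | set[str] = frozenset({"DH"})):
    """Yield (path, locality, lat, lon, elevation_m, n) excluding given paths."""
    for row in LOCALITIES:
        if row[0] not in exclude_paths:
            yield row
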