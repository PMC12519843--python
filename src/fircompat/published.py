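"""Published reference values for Chinese fir aboveground-biomass allometry.

These are the reported coefficients and summary statistics from a large
UAV-LiDAR study of *Cunninghamia lanceolata* plantations in Guangdong,
southern China (20,836 trees across five stand-age groups).  They serve two
roles in this package:

* defaults ("truth") for the synthetic stand generator, so that simulated
  data carry a realistic allometric signal, and
* regression anchors for tests: the values are stored verbatim, including
  entries that are internally inconsistent in the published source (see
  :data:`SUSPECT_SUMMARY_ENTRIES`); nothing is silently corrected.

All biomass values are kilograms of dry mass; LiDAR tree height ``lh`` and
crown diameter ``lcd`` are metres.  Age groups are the five Chinese-fir
stand-development classes: 1 young (1-10 y), 2 middle-aged (11-20 y),
3 near-mature (21-25 y), 4 mature (26-35 y), 5 over-mature (>36 y).
"""

from __future__ import annotations

AGE_GROUPS = (1, 2, 3, 4, 5)

#: Biomass components in canonical column order; "total" is always their sum.
COMPONENTS = ("bark", "trunk", "branch", "leaf")
ALL_RESPONSES = COMPONENTS + ("total",)

AGE_GROUP_LABELS = {
    1: "young (1-10 y)",
    2: "middle-aged (11-20 y)",
    3: "near-mature (21-25 y)",
    4: "mature (26-35 y)",
    5: "over-mature (>36 y)",
}

# ---------------------------------------------------------------------------
# Single-equation candidate-form fits (all five age groups pooled).
# Parameter meaning by form:
#   logistic:    BM = a / (1 + b*exp(-c*LH - d*LCD))
#   linear:      BM = a*LH + b*LCD - c
#   exponential: BM = a*exp(-b*LH - c*LCD)
#   power:       BM = a*LH^b*LCD^c
# Signs are exactly as published (e.g. the exponential rows report negative
# b, c so the effective exponents are positive).
# ---------------------------------------------------------------------------
BASE_MODEL_FITS = {
    "logistic": {
        "bark": {
            "params": {"a": 152.4712, "b": 74.0495, "c": 0.1849, "d": 0.1210},
            "se": {"a": 3.0908, "b": 1.6807, "c": 0.0025, "d": 0.0036},
            "train": {"aic": 118516.0, "bic": 118554.0, "r2": 0.6968,
                      "rmse": 14.0616, "tre": 14.7311},
            "test": {"r2": 0.7017, "rmse": 13.8441, "tre": 14.0853},
        },
        "trunk": {
            "params": {"a": 23.0897, "b": 51.4099, "c": 0.1729, "d": 0.1297},
            "se": {"a": 0.4412, "b": 1.0812, "c": 0.0024, "d": 0.0037},
            "train": {"aic": 64684.0, "bic": 64721.0, "r2": 0.6938,
                      "rmse": 2.2213, "tre": 12.2229},
            "test": {"r2": 0.6981, "rmse": 2.1869, "tre": 12.2229},
        },
        "branch": {
            "params": {"a": 31.6152, "b": 37.0484, "c": 0.1477, "d": 0.1911},
            "se": {"a": 0.6479, "b": 0.8338, "c": 0.0024, "d": 0.0048},
            "train": {"aic": 78855.0, "bic": 78893.0, "r2": 0.6172,
                      "rmse": 3.6106, "tre": 15.9090},
            "test": {"r2": 0.6209, "rmse": 3.5423, "tre": 15.0717},
        },
        "leaf": {
            "params": {"a": 12.0925, "b": 13.1769, "c": 0.1164, "d": 0.2228},
            "se": {"a": 0.2203, "b": 0.2831, "c": 0.0025, "d": 0.0062},
            "train": {"aic": 57095.0, "bic": 57133.0, "r2": 0.5346,
                      "rmse": 1.7125, "tre": 12.1670},
            "test": {"r2": 0.5355, "rmse": 1.6915, "tre": 11.7104},
        },
        "total": {
            "params": {"a": 222.2174, "b": 54.6878, "c": 0.1699, "d": 0.1358},
            "se": {"a": 4.5191, "b": 1.1468, "c": 0.0023, "d": 0.0037},
            "train": {"aic": 130137.0, "bic": 130175.0, "r2": 0.6862,
                      "rmse": 20.9428, "tre": 13.6838},
            "test": {"r2": 0.6911, "rmse": 20.5834, "tre": 13.0369},
        },
    },
    "linear": {
        "bark": {
            "params": {"a": 4.4580, "b": 3.4427, "c": -36.5957},
            "se": {"a": 0.0326, "b": 0.0891, "c": 0.4069},
            "train": {"aic": 119805.0, "bic": 119835.0, "r2": 0.6687,
                      "rmse": 14.6976, "tre": 16.3161},
            "test": {"r2": 0.6751, "rmse": 14.4483, "tre": 15.5760},
        },
        "trunk": {
            "params": {"a": 0.6944, "b": 0.5907, "c": -5.2291},
            "se": {"a": 0.0051, "b": 0.0138, "c": 0.0633},
            "train": {"aic": 65453.0, "bic": 65483.0, "r2": 0.6772,
                      "rmse": 2.2808, "tre": 13.5626},
            "test": {"r2": 0.6728, "rmse": 2.2417, "tre": 12.9435},
        },
        "branch": {
            "params": {"a": 0.8556, "b": 1.2093, "c": -6.2027},
            "se": {"a": 0.0081, "b": 0.0221, "c": 0.1011},
            "train": {"aic": 79155.0, "bic": 79185.0, "r2": 0.6092,
                      "rmse": 3.6481, "tre": 16.2959},
            "test": {"r2": 0.6145, "rmse": 3.5723, "tre": 15.3925},
        },
        "leaf": {
            "params": {"a": 0.3155, "b": 0.5897, "c": -0.9447},
            "se": {"a": 0.0038, "b": 0.0104, "c": 0.0476},
            "train": {"aic": 57008.0, "bic": 57038.0, "r2": 0.5373,
                      "rmse": 1.7075, "tre": 12.0880},
            "test": {"r2": 0.5392, "rmse": 1.6846, "tre": 11.6163},
        },
        "total": {
            "params": {"a": 6.3235, "b": 5.8324, "c": -48.9722},
            "se": {"a": 0.0479, "b": 0.1311, "c": 0.5986},
            "train": {"aic": 131043.0, "bic": 131073.0, "r2": 0.6660,
                      "rmse": 21.6046, "tre": 14.6914},
            "test": {"r2": 0.6723, "rmse": 21.2003, "tre": 13.9661},
        },
    },
    "exponential": {
        "bark": {
            "params": {"a": 5.2187, "b": -0.1140, "c": -0.0580},
            "se": {"a": 0.0672, "b": 0.0007, "c": 0.0016},
            "train": {"aic": 119897.0, "bic": 119927.0, "r2": 0.6666,
                      "rmse": 14.7439, "tre": 16.4360},
            "test": {"r2": 0.6772, "rmse": 14.4000, "tre": 15.4322},
        },
        "trunk": {
            "params": {"a": 1.0704, "b": -0.1033, "c": -0.5915},
            "se": {"a": 0.0126, "b": 0.0007, "c": 0.0016},
            "train": {"aic": 66102.0, "bic": 66133.0, "r2": 0.6624,
                      "rmse": 2.3322, "tre": 14.2688},
            "test": {"r2": 0.6715, "rmse": 2.2812, "tre": 13.4594},
        },
        "branch": {
            "params": {"a": 1.8708, "b": -0.0884, "c": -0.0819},
            "se": {"a": 0.0241, "b": 0.0008, "c": 0.0017},
            "train": {"aic": 80057.0, "bic": 80087.0, "r2": 0.5843,
                      "rmse": 3.7627, "tre": 17.5174},
            "test": {"r2": 0.5933, "rmse": 3.6692, "tre": 16.4382},
        },
        "leaf": {
            "params": {"a": 1.8960, "b": -0.1027, "c": -0.0517},
            "se": {"a": 0.0178, "b": 0.0007, "c": 0.0016},
            "train": {"aic": 80235.0, "bic": 80266.0, "r2": 0.6736,
                      "rmse": 3.7858, "tre": 12.9121},
            "test": {"r2": 0.6814, "rmse": 3.7180, "tre": 12.2863},
        },
        "total": {
            "params": {"a": 9.4116, "b": -0.1045, "c": -0.0634},
            "se": {"a": 0.1147, "b": 0.0008, "c": 0.0016},
            "train": {"aic": 131449.0, "bic": 131479.0, "r2": 0.6566,
                      "rmse": 21.9076, "tre": 15.1694},
            "test": {"r2": 0.6668, "rmse": 21.3776, "tre": 14.2346},
        },
    },
    "power": {
        "bark": {
            "params": {"a": 0.1312, "b": 2.0123, "c": 0.1932},
            "se": {"a": 0.0051, "b": 0.0136, "c": 0.0051},
            "train": {"aic": 118537.0, "bic": 118567.0, "r2": 0.6963,
                      "rmse": 14.0724, "tre": 14.7571},
            "test": {"r2": 0.7133, "rmse": 13.8063, "tre": 13.9398},
        },
        "trunk": {
            "params": {"a": 0.0636, "b": 1.8773, "c": 0.1752},
            "se": {"a": 0.0015, "b": 0.0124, "c": 0.0047},
            "train": {"aic": 83695.0, "bic": 83726.0, "r2": 0.6994,
                      "rmse": 2.2056, "tre": 13.0076},
            "test": {"r2": 0.7052, "rmse": 2.2386, "tre": 12.3850},
        },
        "branch": {
            "params": {"a": 0.1302, "b": 1.4902, "c": 0.2832},
            "se": {"a": 0.0003, "b": 0.0191, "c": 0.0066},
            "train": {"aic": 78998.0, "bic": 79028.0, "r2": 0.6134,
                      "rmse": 3.6286, "tre": 16.0935},
            "test": {"r2": 0.6175, "rmse": 3.5583, "tre": 15.2033},
        },
        "leaf": {
            "params": {"a": 0.3362, "b": 0.9419, "c": 0.2484},
            "se": {"a": 0.0102, "b": 0.0112, "c": 0.0049},
            "train": {"aic": 57404.0, "bic": 57434.0, "r2": 0.5246,
                      "rmse": 1.7308, "tre": 12.4618},
            "test": {"r2": 0.5234, "rmse": 1.7133, "tre": 12.0541},
        },
        "total": {
            "params": {"a": 0.3551, "b": 1.8102, "c": 0.2109},
            "se": {"a": 0.0129, "b": 0.0129, "c": 0.0049},
            "train": {"aic": 130208.0, "bic": 130238.0, "r2": 0.6846,
                      "rmse": 20.9950, "tre": 13.7616},
            "test": {"r2": 0.6909, "rmse": 20.5870, "tre": 12.9989},
        },
    },
}

# Note on row labelling: the published bark/trunk rows above carry RMSE
# magnitudes (≈14 vs ≈2.2) inconsistent with bark being the much smaller
# biomass pool; the two rows may be label-swapped in the source.  They are
# stored under their printed labels without correction.
BASE_MODEL_LABEL_CAVEAT = ("bark", "trunk")

# ---------------------------------------------------------------------------
# Age-group dummy-variable power fits: per-group scale coefficients
# a1..a5 with exponents b (on LH) and c (on LCD) shared across groups.
# ---------------------------------------------------------------------------
DUMMY_MODEL_FITS = {
    "bark": {
        "scales": {1: 0.2221, 2: 0.2034, 3: 0.1929, 4: 0.2582, 5: 0.2524},
        "exp_lh": 1.8152, "exp_lcd": 0.1936,
        "se_scales": {1: 0.0094, 2: 0.0097, 3: 0.0093, 4: 0.0129, 5: 0.0123},
        "se_exp_lh": 0.0178, "se_exp_lcd": 0.0049,
        "train": {"r2": 0.7193, "rmse": 13.5287, "tre": 13.4880},
        "test": {"r2": 0.7198, "rmse": 13.4717, "tre": 13.0373},
    },
    "trunk": {
        "scales": {1: 0.0682, 2: 0.0627, 3: 0.0598, 4: 0.0781, 5: 0.0763},
        "exp_lh": 1.6104, "exp_lcd": 0.1939,
        "se_scales": {1: 0.0027, 2: 0.0026, 3: 0.0027, 4: 0.0036, 5: 0.0035},
        "se_exp_lh": 0.0164, "se_exp_lcd": 0.0046,
        "train": {"r2": 0.7147, "rmse": 2.1441, "tre": 11.7994},
        "test": {"r2": 0.7140, "rmse": 2.1287, "tre": 11.4484},
    },
    "branch": {
        "scales": {1: 0.2290, 2: 0.2088, 3: 0.2024, 4: 0.2756, 5: 0.2635},
        "exp_lh": 1.2731, "exp_lcd": 0.2870,
        "se_scales": {1: 0.0099, 2: 0.0098, 3: 0.0101, 4: 0.0141, 5: 0.0132},
        "se_exp_lh": 0.0181, "se_exp_lcd": 0.0055,
        "train": {"r2": 0.6434, "rmse": 3.4849, "tre": 14.6613},
        "test": {"r2": 0.6403, "rmse": 3.4507, "tre": 14.1326},
    },
    "leaf": {
        "scales": {1: 0.4902, 2: 0.4537, 3: 0.4476, 4: 0.5695, 5: 0.5447},
        "exp_lh": 0.7961, "exp_lcd": 0.2508,
        "se_scales": {1: 0.0176, 2: 0.0175, 3: 0.0187, 4: 0.0246, 5: 0.0231},
        "se_exp_lh": 0.0151, "se_exp_lcd": 0.0048,
        "train": {"r2": 0.5533, "rmse": 1.6777, "tre": 11.6213},
        "test": {"r2": 0.5461, "rmse": 1.6720, "tre": 11.3978},
    },
    "total": {
        "scales": {1: 0.5919, 2: 0.5405, 3: 0.5156, 4: 0.6873, 5: 0.6685},
        "exp_lh": 1.6189, "exp_lcd": 0.2122,
        "se_scales": {1: 0.0241, 2: 0.0238, 3: 0.0241, 4: 0.0329, 5: 0.0314},
        "se_exp_lh": 0.0169, "se_exp_lcd": 0.0048,
        "train": {"r2": 0.7095, "rmse": 20.1484, "tre": 12.5377},
        "test": {"r2": 0.7091, "rmse": 19.9734, "tre": 12.1172},
    },
}

# ---------------------------------------------------------------------------
# Additivity-constrained SUR system fit: four component equations
#   M_comp = (sum_i scale_i * AG_i) * LH^exp_lh * LCD^exp_lcd
# with the total defined as their exact sum (an identity, not an equation).
# Stored under the component mapping of the system's definition (first row
# = trunk); the published trunk/bark coefficient magnitudes mirror the
# dummy-model bark/trunk rows respectively, consistent with the same
# label-swap caveat as above — values are kept verbatim.
# ---------------------------------------------------------------------------
SUR_SYSTEM_FIT = {
    "trunk": {
        "scales": {1: 0.2124, 2: 0.1964, 3: 0.1904, 4: 0.2517, 5: 0.2438},
        "exp_lh": 1.8021, "exp_lcd": 0.2035,
        "r2": 0.7042, "rmse": 13.6057,
    },
    "bark": {
        "scales": {1: 0.1098, 2: 0.1016, 3: 0.0991, 4: 0.1289, 5: 0.1242},
        "exp_lh": 1.4594, "exp_lcd": 0.2122,
        "r2": 0.6927, "rmse": 2.2191,
    },
    "branch": {
        "scales": {1: 0.2901, 2: 0.2662, 3: 0.2634, 4: 0.3614, 5: 0.3392},
        "exp_lh": 1.1792, "exp_lcd": 0.2989,
        "r2": 0.6345, "rmse": 3.4749,
    },
    "leaf": {
        "scales": {1: 0.3401, 2: 0.3522, 3: 0.3464, 4: 0.4599, 5: 0.4372},
        "exp_lh": 0.9358, "exp_lcd": 0.2524,
        "r2": 0.5316, "rmse": 1.7175,
    },
    "total": {"r2": 0.6835, "rmse": 20.9835},  # identity row: sum of components
}

# ---------------------------------------------------------------------------
# Field biomass summary by age group (kg): (max, min, mean, sd) for the
# 70% training and 30% test partitions.
# ---------------------------------------------------------------------------
BIOMASS_SUMMARY = {
    (1, "bark"): {"train": (13.1381, 0.1096, 3.3632, 2.1627),
                  "test": (13.6484, 0.1078, 3.3480, 2.1404)},
    (1, "trunk"): {"train": (82.1074, 0.4052, 17.8427, 12.5648),
                   "test": (82.2535, 0.3908, 17.7663, 12.3915)},
    (1, "branch"): {"train": (24.0875, 0.1859, 5.4190, 3.5186),
                    "test": (20.7011, 0.1999, 5.3753, 3.5153)},
    (1, "leaf"): {"train": (12.6573, 0.2178, 3.6598, 1.8578),
                  "test": (11.6341, 0.3181, 3.6286, 1.8696)},
    (1, "total"): {"train": (121.232, 1.032, 30.285, 19.8221),
                   "test": (126.284, 1.0660, 30.118, 19.63353)},
    (2, "bark"): {"train": (27.7597, 0.1905, 4.2946, 2.6693),
                  "test": (18.4729, 0.1616, 4.2767, 2.7001)},
    (2, "trunk"): {"train": (114.5734, 0.2389, 23.7724, 16.2536),
                   "test": (117.290, 0.664, 23.706, 16.5119)},
    (2, "branch"): {"train": (27.7597, 0.1905, 6.3721, 4.0636),
                    "test": (26.7768, 0.1962, 6.3189, 4.0678)},
    (2, "leaf"): {"train": (13.1418, 0.3621, 3.9614, 1.9822),
                  "test": (12.3967, 0.2959, 3.9307, 1.9809)},
    (2, "total"): {"train": (167.7102, 0.9027, 38.4005, 24.5177),
                   "test": (172.002, 1.3180, 38.2320, 24.7832)},
    (3, "bark"): {"train": (18.203, 0.2100, 5.6330, 3.1345),
                  "test": (17.3344, 0.2384, 5.6755, 3.2327)},
    (3, "trunk"): {"train": (119.9051, 0.8125, 5.6330, 19.4172),
                   "test": (119.5493, 32.4140, 32.4140, 20.2089)},
    (3, "branch"): {"train": (30.9941, 0.3836, 8.1419, 4.7029),
                    "test": (28.8945, 0.3809, 8.1836, 4.7461)},
    (3, "leaf"): {"train": (13.8340, 0.5250, 4.6920, 2.1299),
                  "test": (13.3614, 0.5477, 4.7083, 2.1188)},
    (3, "total"): {"train": (172.8820, 1.9910, 50.5760, 28.9169),
                   "test": (170.803, 2.126, 50.9810, 29.8144)},
    (4, "bark"): {"train": (30.2370, 0.3516, 9.6597, 5.0867),
                  "test": (29.1160, 0.5170, 9.6740, 5.1307)},
    (4, "trunk"): {"train": (202.511, 1.415, 58.025, 33.8275),
                   "test": (202.1930, 2.2330, 9.6740, 34.2114)},
    (4, "branch"): {"train": (43.9100, 0.6700, 13.9670, 7.3899),
                    "test": (41.6285, 0.5713, 13.9616, 7.4742)},
    (4, "leaf"): {"train": (20.7530, 0.8990, 6.9680, 2.8834),
                  "test": (17.8720, 0.6087, 6.9545, 2.9362)},
    (4, "total"): {"train": (288.847, 3.3350, 88.6200, 48.1882),
                   "test": (276.6640, 4.1920, 88.7440, 48.6847)},
    (5, "bark"): {"train": (28.2904, 0.3132, 8.9868, 5.1823),
                  "test": (32.9320, 0.2010, 8.9860, 5.1799)},
    (5, "trunk"): {"train": (196.453, 1.1780, 54.831, 34.1049),
                   "test": (219.7082, 0.7777, 53.8313, 34.1237)},
    (5, "branch"): {"train": (41.3550, 0.5135, 6.4952, 7.3607),
                    "test": (47.2662, 0.3596, 12.9217, 7.4495)},
    (5, "leaf"): {"train": (16.7751, 0.7119, 6.4952, 2.8506),
                  "test": (17.1669, 0.4503, 6.5330, 2.9408)},
    (5, "total"): {"train": (279.8830, 2.6970, 82.1660, 48.7637),
                   "test": (316.848, 1.891, 82.272, 48.8275)},
}

#: Entries of BIOMASS_SUMMARY that are internally inconsistent in the
#: published source (apparent typographic duplications).  Flagged, kept
#: verbatim, and excluded from calibration/consistency checks.
SUSPECT_SUMMARY_ENTRIES = (
    (3, "trunk", "train", "mean"),   # duplicates the bark mean 5.6330
    (3, "trunk", "test", "min"),     # duplicates its own mean 32.4140
    (4, "trunk", "test", "mean"),    # duplicates the bark mean 9.6740
    (5, "branch", "train", "mean"),  # duplicates the leaf mean 6.4952
    (2, "branch", "train", "max"),   # duplicates the bark max 27.7597
    (2, "branch", "train", "min"),   # duplicates the bark min 0.1905
)

#: (age_group, sample) rows of BIOMASS_SUMMARY whose component means add up
#: to the published total mean (within print rounding); the remaining rows
#: are poisoned by the suspect entries above.
ADDITIVE_SUMMARY_ROWS = (
    (1, "train"), (1, "test"),
    (2, "train"), (2, "test"),
    (4, "train"),
    (5, "test"),
)

# ---------------------------------------------------------------------------
# UAV-LiDAR covariate summary (m): (max, min, mean, sd).
# ---------------------------------------------------------------------------
LIDAR_SUMMARY = {
    "lh": {"train": (31.6296, 2.9455, 13.1114, 4.0801),
           "test": (28.771, 2.7577, 13.1416, 4.0674)},
    "lcd": {"train": (16.474, 0.13624, 2.3081, 1.4899),
            "test": (12.046, 0.1612, 2.3401, 1.5169)},
}

#: Reported sample sizes: total trees, plots, and the per-age-group counts
#: that were published (only the youngest and oldest groups are reported).
STUDY_SAMPLE = {
    "n_trees": 20836,
    "n_plots": 133,
    "n_age_group_1": 7481,
    "n_age_group_5": 1885,
}
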