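"""Frozen calibration anchors for the synthetic cohort generator.

These constants are the published group-level summaries of the Slovene
clinical verbal-fluency cohort that the generator emulates: group sizes,
word-accuracy summaries of the best-performing ASR system at each
transcript level, automated refinement/tagging rates, and the
group-comparison summaries of the top-ranked features.  Group standard
deviations are back-derived from the printed 95% HDIs of the posterior
group means: sd = HDI half-width / 1.96 * sqrt(n_group).

Everything else the generator needs (distribution families, token
durations, clustering behavior, non-anchored acoustic descriptors) has
no published value and is a documented artifact choice; see
docs/methods.md.
"""

from __future__ import annotations

from math import sqrt

GROUP_N = {"HC": 68, "SH": 58}

# Per-group WAcc means at unprocessed / filtered / adjusted levels
# (best-performing ASR system).
WACC_MEANS = {
    "HC": {"U": 0.49, "F": 0.73, "A": 0.75},
    "SH": {"U": 0.24, "F": 0.49, "A": 0.52},
}
# Adjusted-level 95% HDIs of the posterior group means (used for the
# Bayesian-certainty simulation and for back-derived SDs).
WACC_ADJUSTED = {
    "HC": (0.75, (0.70, 0.79)),
    "SH": (0.52, (0.45, 0.59)),
}

# Automated refinement rates, percent, token-weighted pooled.
RETENTION_PCT = {  # |F| / |U| * 100
    ("HC", "phonetic"): 63.06,
    ("SH", "phonetic"): 82.64,
    ("HC", "semantic"): 84.59,
    ("SH", "semantic"): 72.90,
}
OVERLAP_PCT = {  # share of F tokens textually unchanged in A
    ("HC", "phonetic"): 94.81,
    ("SH", "phonetic"): 79.56,
    ("HC", "semantic"): 94.55,
    ("SH", "semantic"): 80.50,
}

# Automated semantic-tagging rates, percent of tokens.
INTRUSION_PCT = {
    ("HC", "phonetic"): 9.31,
    ("SH", "phonetic"): 20.65,
    ("HC", "semantic"): 2.78,
    ("SH", "semantic"): 8.53,
}
NEOLOGISM_PCT = {
    ("HC", "phonetic"): 0.16,
    ("SH", "phonetic"): 0.93,
    ("HC", "semantic"): 0.00,
    ("SH", "semantic"): 1.27,
}

# Group-comparison anchors of the top-ranked features:
# feature id -> (mu_h, hdi_h, mu_s, hdi_s, p_r, dd)
FEATURE_ANCHORS = {
    "V1": (0.36, (0.33, 0.39), 0.19, (0.15, 0.23), 0.83, 0.33),
    "V3": (0.20, (0.17, 0.23), 0.44, (0.38, 0.50), 0.23, 0.27),
    "V16": (0.21, (0.18, 0.23), 0.10, (0.08, 0.12), 0.76, 0.26),
    "N10": (405.84, (345.60, 468.71), 212.20, (160.06, 262.52), 0.75, 0.25),
    "V5": (0.05, (0.04, 0.06), 0.12, (0.10, 0.15), 0.26, 0.24),
    "V6": (0.04, (0.04, 0.04), 0.24, (0.18, 0.30), 0.26, 0.24),
    "V27": (0.29, (0.27, 0.32), 0.19, (0.14, 0.24), 0.73, 0.23),
    "N3": (277.60, (243.12, 314.33), 169.71, (141.11, 197.86), 0.73, 0.23),
    "V30": (0.14, (0.12, 0.16), 0.09, (0.06, 0.12), 0.73, 0.23),
    "V39": (0.97, (0.96, 0.98), 0.89, (0.86, 0.92), 0.72, 0.22),
    "N8": (281.42, (239.80, 324.92), 177.05, (129.23, 228.00), 0.71, 0.21),
}

# Directional group pattern implied by the anchors (True: HC > SH).
ANCHOR_DIRECTION_HC_GREATER = {
    "V1": True, "V3": False, "V16": True, "V27": True, "V30": True, "V39": True,
}


def sd_from_hdi(hdi: tuple[float, float], n: int) -> float:
    """Back-derive a group sample SD from the HDI of its posterior mean.

    The HDI half-width of a posterior *mean* scales like sd / sqrt(n),
    so sd = half-width / 1.96 * sqrt(n).
    """
    half = (hdi[1] - hdi[0]) / 2.0
    return half / 1.96 * sqrt(n)


def anchor_mean_sd(feature_id: str, group: str) -> tuple[float, float]:
    """(group mean, back-derived group SD) for an anchored feature."""
    mu_h, hdi_h, mu_s, hdi_s, _, _ = FEATURE_ANCHORS[feature_id]
    if group == "HC":
        return mu_h, sd_from_hdi(hdi_h, GROUP_N["HC"])
    if group == "SH":
        return mu_s, sd_from_hdi(hdi_s, GROUP_N["SH"])
    raise KeyError(group)
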