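"""Built-in coefficient tables for the three sexes and the micronutrient fit points.

All numbers are transcribed model constants; nothing in this module computes.
Keys are lowercase snake_case throughout.
"""

from __future__ import annotations

SEXES = ("gilt", "barrow", "boar")

# Protein-deposition cubic, g/d: a * (b + c*BW + d*BW^2 + e*BW^3)
PD_CUBIC = {
    "gilt": {"a": 137.0, "b": 0.7066, "c": 0.013289, "d": -1.3120e-4, "e": 2.8627e-7},
    "barrow": {"a": 133.0, "b": 0.7078, "c": 0.013764, "d": -1.4211e-4, "e": 3.2698e-7},
    "boar": {"a": 151.0, "b": 0.6558, "c": 0.012740, "d": -1.0390e-4, "e": 1.64001e-7},
}

# Metabolizable energy intake curve, kcal/d: a * (1 - exp(-exp(b) * BW^c))
MEI_COEFFS = {
    "gilt": {"a": 10967.0, "b": -3.803, "c": 0.9072},
    "barrow": {"a": 10447.0, "b": -4.283, "c": 1.0843},
    "boar": {"a": 10638.0, "b": -3.803, "c": 0.9072},
}

# Feed intake curve, kg/d: x * (1 - exp(-exp(y) * BW^z)).
# No intake curve is available for boars; their feed intake is derived from
# energy instead (see energy.feed_intake).
FI_COEFFS = {
    "gilt": {"x": 2.755, "y": -4.755, "z": 1.214},
    "barrow": {"x": 2.88, "y": -5.921, "z": 1.512},
    "boar": None,
}

# Default body-weight-gain polynomial, g/d: c0 + c1*BW + c2*BW^2.
# A single polynomial is shipped; per-sex overrides go through HerdConfig.
DEFAULT_BWG_COEFFS = (485.17, 8.8503, -0.0477)

# Essential amino acids (and nitrogen) as fractions of the SID lysine requirement.
AA_RATIOS = {
    "arginine": 0.457,
    "histidine": 0.344,
    "isoleucine": 0.522,
    "leucine": 1.007,
    "methionine": 0.289,
    "methionine+cysteine": 0.564,
    "phenylalanine": 0.597,
    "phenylalanine+tyrosine": 0.938,
    "threonine": 0.603,
    "tryptophan": 0.171,
    "valine": 0.649,
    "nitrogen": 2.148,
}

# Reference body weights (kg) at which the per-sex micronutrient requirement
# values below were reported: (gilt, barrow, boar).
MICRONUTRIENT_REFERENCE_BWS = (126.55, 127.99, 123.55)

# nutrient -> (class, units, (value_at_gilt_bw, value_at_barrow_bw, value_at_boar_bw))
MICRONUTRIENT_POINTS = {
    "sodium": ("mineral", "g/d", (2.92, 2.94, 2.90)),
    "chlorine": ("mineral", "g/d", (2.31, 2.32, 2.29)),
    "magnesium": ("mineral", "g/d", (1.15, 1.16, 1.14)),
    "potassium": ("mineral", "g/d", (4.75, 4.76, 4.73)),
    "copper": ("mineral", "mg/d", (8.46, 8.48, 8.41)),
    "iodine": ("mineral", "mg/d", (0.40, 0.40, 0.40)),
    "iron": ("mineral", "mg/d", (111.34, 111.52, 110.96)),
    "manganese": ("mineral", "mg/d", (5.79, 5.82, 5.74)),
    "selenium": ("mineral", "mg/d", (0.41, 0.42, 0.41)),
    "zinc": ("mineral", "mg/d", (140.96, 141.45, 139.91)),
    "vitamin_a": ("vitamin", "IU/d", (3767.85, 3784.44, 3732.48)),
    "vitamin_d3": ("vitamin", "IU/d", (434.76, 436.67, 430.68)),
    "vitamin_e": ("vitamin", "IU/d", (31.88, 32.02, 31.58)),
    "vitamin_k": ("vitamin", "mg/d", (1.44, 1.45, 1.43)),
    "biotin": ("vitamin", "mg/d", (0.14, 0.14, 0.14)),
    "choline": ("vitamin", "g/d", (0.86, 0.87, 0.86)),
    "folacin": ("vitamin", "mg/d", (0.86, 0.87, 0.86)),
    "niacin": ("vitamin", "mg/d", (86.95, 87.33, 86.13)),
    "pantothenic_acid": ("vitamin", "mg/d", (19.89, 19.96, 19.73)),
    "riboflavin": ("vitamin", "mg/d", (5.59, 5.61, 5.56)),
    "thiamin": ("vitamin", "mg/d", (2.89, 2.91, 2.87)),
    "vitamin_b6": ("vitamin", "mg/d", (2.89, 2.91, 2.87)),
    "vitamin_b12": ("vitamin", "ug/d", (12.51, 12.50, 12.53)),
    "linoleic_acid": ("vitamin", "g/d", (2.89, 2.91, 2.87)),
}

# Reference maximum protein deposition (g/d) used as the anchor point in the
# lysine-efficiency denominator. Fixed constant, never recomputed.
PD_MAX_REFERENCE = 147.7

# Energetic cost of deposition, kcal ME per g deposited.
KCAL_PER_G_PROTEIN = 10.6
KCAL_PER_G_LIPID = 12.5
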