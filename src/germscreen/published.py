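"""Reference values from the published 552-line sunflower germination-stage
screening, for verification and for scoring new germplasms against the
published panel.

``PUBLISHED_STI_ROWS`` holds the printed verification set: three germplasms
from each of the five grades with their seven STIs, mean MFV and Y score.
``PUBLISHED_MFV_ROWS`` holds the five most tolerant and five most sensitive
lines with their per-trait MFVs, mean MFV and grade.  Values carry the
printed rounding (3 decimals for STI/MFV, 5 for mean MFV and Y).
"""

from __future__ import annotations

from .panel_io import TRAITS

__all__ = ["PUBLISHED_STI_ROWS", "PUBLISHED_MFV_ROWS"]

# germplasm -> (STI_GR, STI_GI, STI_GE, STI_RL, STI_GVI, STI_FW, STI_WC,
#               mean MFV, Y)
PUBLISHED_STI_ROWS: dict[str, tuple[tuple[float, ...], float, float]] = {
    "152505": ((0.936, 0.836, 0.676, 0.230, 0.193, 1.087, 1.228), 0.71509, 0.71629),
    "156004": ((0.933, 0.665, 0.303, 0.404, 0.269, 1.010, 1.225), 0.68799, 0.68987),
    "156017": ((0.913, 0.637, 0.319, 0.451, 0.287, 0.901, 1.111), 0.67721, 0.67925),
    "156008": ((0.741, 0.479, 0.154, 0.424, 0.203, 0.602, 0.763), 0.50170, 0.50320),
    "152478": ((0.876, 0.785, 0.688, 0.115, 0.091, 0.449, 0.499), 0.49922, 0.49972),
    "152533": ((0.758, 0.686, 0.636, 0.175, 0.120, 0.517, 0.588), 0.49903, 0.49977),
    "152209": ((0.879, 0.424, 0.030, 0.166, 0.071, 0.728, 0.824), 0.41223, 0.41273),
    "151156": ((0.970, 0.607, 0.061, 0.101, 0.061, 0.535, 0.771), 0.41185, 0.41222),
    "152101": ((0.727, 0.505, 0.152, 0.176, 0.089, 0.643, 0.738), 0.41182, 0.41240),
    "156023": ((0.289, 0.143, 0.024, 0.152, 0.022, 0.105, 0.124), 0.12933, 0.12953),
    "151072": ((0.107, 0.043, 0.000, 0.135, 0.006, 0.019, 0.847), 0.12925, 0.12924),
    "152044": ((0.364, 0.182, 0.030, 0.108, 0.020, 0.060, 0.071), 0.12675, 0.12693),
    "152059": ((0.061, 0.015, 0.000, 0.099, 0.001, 0.042, 0.048), 0.04172, 0.04177),
    "152069": ((0.091, 0.022, 0.000, 0.113, 0.003, 0.000, 0.000), 0.04115, 0.04122),
    "152237": ((0.091, 0.022, 0.000, 0.081, 0.002, 0.027, 0.032), 0.04016, 0.04021),
}

# germplasm -> (MFV_GR..MFV_WC, mean MFV, grade)
PUBLISHED_MFV_ROWS: dict[str, tuple[tuple[float, ...], float, str]] = {
    "152505": ((0.936, 0.856, 0.719, 0.343, 0.488, 0.905, 0.758), 0.715, "HST"),
    "156004": ((0.933, 0.681, 0.323, 0.602, 0.681, 0.841, 0.756), 0.688, "HST"),
    "156017": ((0.913, 0.652, 0.340, 0.672, 0.728, 0.751, 0.685), 0.677, "HST"),
    "151082": ((1.000, 1.000, 1.000, 0.177, 0.294, 0.660, 0.539), 0.667, "HST"),
    "151040": ((0.633, 0.635, 0.639, 0.876, 0.925, 0.260, 0.580), 0.650, "HST"),
    "152012": ((0.030, 0.002, 0.000, 0.085, 0.000, 0.000, 0.000), 0.017, "HSS"),
    "152021": ((0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000), 0.000, "HSS"),
    "152094": ((0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000), 0.000, "HSS"),
    "156084": ((0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000), 0.000, "HSS"),
    "156096": ((0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000), 0.000, "HSS"),
}

assert all(len(r[0]) == len(TRAITS) for r in PUBLISHED_STI_ROWS.values())
assert all(len(r[0]) == len(TRAITS) for r in PUBLISHED_MFV_ROWS.values())
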