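"""Published summary statistics of the Macaronesian *Octopus vulgaris*
mitochondrial control-region survey (six NE-Atlantic sampling sites).

These printed values — per-site diversity and mismatch parameters, the
pairwise F_ST matrix, site coordinates, and the dating-chain inputs — let
the differentiation, isolation-by-distance and dating arithmetic be
exercised without access to the underlying sequence data ("printed-inputs
mode").  They are inputs, not test expectations: downstream numbers are
always recomputed from them.

Coordinate note: latitudes were printed in a degree/minute style with one
entry ("32°63'") whose minute field exceeds 59 and is only meaningful as a
decimal fraction; it is stored as 32.63°.  All other latitudes are converted
from degrees+minutes; longitudes are printed decimals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SITES = ["Galicia", "Azores", "Madeira", "Canaries", "Morocco", "CaboVerde"]

#: site -> (latitude, longitude) in decimal degrees
COORDINATES = {
    "Galicia": (42.0 + 20.0 / 60.0, -8.88),
    "Azores": (38.0 + 54.0 / 60.0, -28.57),
    "Madeira": (32.63, -16.91),
    "Canaries": (28.0 + 6.0 / 60.0, -16.03),
    "Morocco": (31.0 + 41.0 / 60.0, -9.85),
    "CaboVerde": (16.0 + 6.0 / 60.0, -23.07),
}

#: per-site summary: n, distinct haplotypes, h, pi, and sudden-model
#: mismatch fit (tau, theta0, theta1), neutrality statistics with P-values,
#: Harpending's raggedness and SSD with bootstrap P-values
SITE_STATS = pd.DataFrame(
    [
        # site, n, k, h, pi, tajima_D, p_D, fu_Fs, p_Fs, tau, theta0, theta1, ragg, p_ragg, SSD, p_SSD
        ("Galicia", 50, 12, 0.7861, 0.0018, -1.56349, 0.042, -6.6682, 0.0001, 1.396, 0.001, 99999.0, 0.10132, 0.074, 0.00889, 0.121),
        ("Azores", 52, 13, 0.6531, 0.0097, 0.13457, 0.64, 1.61851, 0.756, 0.0, 0.0, 99999.0, 0.08998, 1.0, 0.51092, 0.0),
        ("Madeira", 50, 13, 0.7845, 0.0190, 2.97211, 0.99, 6.33245, 0.961, 26.34, 0.0, 3.297, 0.08792, 0.399, 0.11399, 0.109),
        ("Canaries", 44, 11, 0.7072, 0.0165, 1.78177, 0.979, 6.10507, 0.957, 25.965, 0.0, 2.237, 0.11287, 0.45, 0.09515, 0.211),
        ("Morocco", 48, 17, 0.8573, 0.0199, 1.74451, 0.971, 2.5078, 0.836, 28.289, 0.002, 24.464, 0.06751, 0.001, 0.07090, 0.027),
        ("CaboVerde", 52, 21, 0.8771, 0.0049, -0.85599, 0.22, -10.69547, 0.0, 4.061, 0.007, 10.542, 0.02803, 0.56, 0.00939, 0.386),
    ],
    columns=[
        "site", "n", "k", "h", "pi", "tajima_D", "p_D", "fu_Fs", "p_Fs",
        "tau", "theta0", "theta1", "raggedness", "p_raggedness", "SSD", "p_SSD",
    ],
).set_index("site")

#: lower-triangle pairwise F_ST with permutation significance at alpha=0.05
#: (10,100 permutations); the two non-significant pairs are Madeira–Canaries
#: and Madeira–Morocco
FST_PAIRS = {
    ("Galicia", "Azores"): (0.07989, True),
    ("Galicia", "Madeira"): (0.14193, True),
    ("Galicia", "Canaries"): (0.18820, True),
    ("Galicia", "Morocco"): (0.12521, True),
    ("Galicia", "CaboVerde"): (0.16822, True),
    ("Azores", "Madeira"): (0.11913, True),
    ("Azores", "Canaries"): (0.16347, True),
    ("Azores", "Morocco"): (0.12365, True),
    ("Azores", "CaboVerde"): (0.23492, True),
    ("Madeira", "Canaries"): (-0.00739, False),
    ("Madeira", "Morocco"): (0.02039, False),
    ("Madeira", "CaboVerde"): (0.16903, True),
    ("Canaries", "Morocco"): (0.02848, True),
    ("Canaries", "CaboVerde"): (0.20614, True),
    ("Morocco", "CaboVerde"): (0.13276, True),
}

#: dating-chain inputs
ALIGNMENT_LENGTH = 637          # control-region sites
GENERATION_YEARS = 0.57         # generation time, years
GEMINATE_P_DISTANCE = 0.06      # net COX1 p-distance across the Isthmus
ISTHMUS_CLOSURE_MY = (3.5, 2.5)  # candidate closure dates
MU_COX1_PER_SITE_MY = 0.0154    # clock-calibrated COX1 rate, subs/site/My
THETA_COX1 = 3.486              # per-locus theta, 42-specimen subsample
THETA_CR = 12.317               # per-locus theta, same specimens
#: sudden/spatial-model tau per haplogroup (mutational units)
TAU_ALPHA_SPATIAL = 4.114
TAU_BETA_SUDDEN = 1.191
TAU_BETA_SPATIAL = 0.781

#: whole-survey figures
TOTAL_SEQUENCES = 296
TOTAL_HAPLOTYPES = 64
OVERALL_H = 0.8783
OVERALL_PI = 0.02039


def fst_matrix() -> tuple[list[str], np.ndarray, np.ndarray]:
    """(site order, symmetric F_ST matrix, boolean significance matrix)."""
    k = len(SITES)
    fst = np.zeros((k, k))
    sig = np.zeros((k, k), dtype=bool)
    for (a, b), (v, s) in FST_PAIRS.items():
        i, j = SITES.index(a), SITES.index(b)
        fst[i, j] = fst[j, i] = v
        sig[i, j] = sig[j, i] = s
    return list(SITES), fst, sig


def coordinates_frame() -> pd.DataFrame:
    """Site coordinate table shaped like :func:`mitopop.seqio.site_table` output."""
    return pd.DataFrame(
        {
            "latitude": [COORDINATES[s][0] for s in SITES],
            "longitude": [COORDINATES[s][1] for s in SITES],
            "n": SITE_STATS.loc[SITES, "n"].to_numpy(),
        },
        index=pd.Index(SITES, name="site"),
    )
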