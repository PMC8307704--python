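"""Published group-level summary statistics used as simulator defaults and oracles.

The source study (rat dorsal skin incisions pretreated with 0.015/0.03/0.045 %
N-acetylcysteine in the anesthetic solution, vs. plain anesthetic control)
reports its histomorphometry only as group means ± SD per harvest day.  Those
printed moments are the study's public face of the data — the raw measurements
were never deposited — so they serve here both as the default parameterization
of :mod:`scarkit.simulate` and as the consistency oracle that locks the healing
index formulas in :mod:`scarkit.morphometry`.

Groups: ``CONT`` (plain lidocaine/epinephrine), ``gNAC`` (the three NAC
concentrations pooled after a non-significant three-way comparison), and
``NAC30`` (0.03 % NAC, printed separately at day 7 only).  Units: lengths in
µm, areas in µm².
"""

from __future__ import annotations

import pandas as pd

MEASUREMENTS = ("D", "DPA", "EPI", "L", "N", "NEO", "S", "T", "H", "B")
INDICES = ("SCI", "DCI", "WSI", "GHI", "GCI", "RHI", "MRI", "GRI")

#: (group, day) -> {measurement: (mean, sd)}
MEASUREMENT_MOMENTS: dict[tuple[str, int], dict[str, tuple[float, float]]] = {
    ("CONT", 7): {
        "D": (527.2, 279.3), "DPA": (134280.2, 60364.62), "EPI": (50.9, 13.1),
        "L": (1909.8, 901.6), "N": (1434.4, 196.7), "NEO": (83.6, 23.4),
        "S": (1533.2, 791.5), "T": (915.5, 298.8), "H": (1604.5, 980.1),
        "B": (189079.1, 127604.5),
    },
    ("gNAC", 7): {
        "D": (627.5, 193.2), "DPA": (180923.8, 190501.1), "EPI": (43.3, 11.5),
        "L": (1932.1, 649.9), "N": (1427.2, 169.5), "NEO": (98.8, 24.4),
        "S": (1312.6, 630.3), "T": (802.9, 270.5), "H": (1448.4, 1152.6),
        "B": (155889.7, 140034.4),
    },
    ("NAC30", 7): {
        "D": (558.3, 251.7), "DPA": (353591.2, 314148.8), "EPI": (42.4, 12.2),
        "L": (1471.0, 810.9), "N": (1459.5, 65.5), "NEO": (102.3, 43.85),
        "S": (820.3, 670.0), "T": (794.5, 145.9), "H": (1731.1, 762.5),
        "B": (222271.6, 196386.6),
    },
    ("CONT", 14): {
        "D": (313.0, 96.8), "DPA": (405838.2, 226281.4), "EPI": (44.4, 10.2),
        "L": (1272.9, 484.5), "N": (1404.1, 187.8), "NEO": (110.1, 28.9),
        "S": (1150.8, 541.2), "T": (1289.0, 192.6), "H": (1890.3, 1082.3),
        "B": (652444.9, 293520.0),
    },
    ("gNAC", 14): {
        "D": (375.8, 191.8), "DPA": (550007.5, 508475.6), "EPI": (46.0, 14.3),
        "L": (1382.7, 570.5), "N": (1496.0, 393.1), "NEO": (114.2, 33.2),
        "S": (1268.9, 676.7), "T": (1484.3, 381.8), "H": (1679.2, 1134.4),
        "B": (622769.1, 387104.4),
    },
    ("CONT", 60): {
        "D": (157.2, 98.2), "DPA": (906748.8, 572360.8), "EPI": (28.1, 6.04),
        "L": (793.99, 456.6), "N": (1680.7, 369.3), "NEO": (38.1, 7.82),
        "S": (696.69, 403.1), "T": (1650.1, 435.3), "H": (542.48, 248.6),
        "B": (619803.1, 407497.9),
    },
    ("gNAC", 60): {
        "D": (143.4, 88.0), "DPA": (743650.1, 336697.1), "EPI": (28.4, 5.21),
        "L": (919.22, 815.1), "N": (1625.0, 246.4), "NEO": (37.3, 12.9),
        "S": (836.99, 776.4), "T": (1542.3, 275.6), "H": (736.08, 705.2),
        "B": (645390.3, 409208.7),
    },
}

#: (group, day) -> {index: (mean, sd)} — printed healing/remodeling indices.
INDEX_MOMENTS: dict[tuple[str, int], dict[str, tuple[float, float]]] = {
    ("CONT", 7): {
        "SCI": (0.21, 0.15), "DCI": (0.63, 0.15), "WSI": (0.35, 0.22),
        "GHI": (0.49, 0.32), "GCI": (0.85, 0.21), "RHI": (-2.76, 0.61),
        "MRI": (2.35, 0.67), "GRI": (-2.09, 0.44),
    },
    ("gNAC", 7): {
        "SCI": (0.34, 0.15), "DCI": (0.55, 0.13), "WSI": (0.44, 0.14),
        "GHI": (0.45, 0.31), "GCI": (0.90, 0.21), "RHI": (0.09, 0.71),
        "MRI": (0.17, 0.74), "GRI": (0.13, 0.61),
    },
    ("NAC30", 7): {
        "SCI": (0.46, 0.18), "DCI": (0.62, 0.16), "WSI": (0.45, 0.12),
        "GHI": (0.63, 0.39), "GCI": (1.08, 0.27), "RHI": (-0.07, 0.47),
        "MRI": (-0.17, 1.03), "GRI": (-0.12, 0.51),
    },
    ("CONT", 14): {
        "SCI": (0.11, 0.21), "DCI": (0.77, 0.06), "WSI": (0.09, 0.14),
        "GHI": (0.80, 0.22), "GCI": (0.89, 0.22), "RHI": (-0.17, 0.67),
        "MRI": (-2.45, 1.55), "GRI": (-1.31, 1.06),
    },
    ("gNAC", 14): {
        "SCI": (0.11, 0.25), "DCI": (0.77, 0.07), "WSI": (0.04, 0.17),
        "GHI": (0.84, 0.30), "GCI": (0.88, 0.28), "RHI": (-0.04, 0.70),
        "MRI": (-2.29, 2.04), "GRI": (-1.17, 1.02),
    },
    ("CONT", 60): {
        "SCI": (0.12, 0.08), "DCI": (0.90, 0.06), "WSI": (0.01, 0.11),
        "GHI": (1.01, 0.18), "GCI": (1.02, 0.10), "RHI": (0.66, 0.15),
        "MRI": (-2.27, 2.15), "GRI": (-0.80, 1.11),
    },
    ("gNAC", 60): {
        "SCI": (0.10, 0.07), "DCI": (0.91, 0.05), "WSI": (0.05, 0.10),
        "GHI": (0.96, 0.15), "GCI": (1.01, 0.09), "RHI": (0.54, 0.43),
        "MRI": (-2.41, 2.16), "GRI": (-0.93, 1.22),
    },
}

#: Observation days of the photographic series.
PLANIMETRY_DAYS = (1, 2, 3, 4, 7, 14, 21, 28, 35, 45, 60)

#: Harvest days with usable histomorphometry (day-3 sections were too damaged).
MORPHOMETRY_DAYS = (7, 14, 60)

STUDY_GROUPS = ("CONT", "NAC15", "NAC30", "NAC45")


def measurement_means(group: str, day: int) -> dict[str, float]:
    """Printed measurement means for one (group, day) cell."""
    return {k: v[0] for k, v in MEASUREMENT_MOMENTS[(group, day)].items()}


def measurement_table() -> pd.DataFrame:
    """All printed measurement moments as a tidy frame (group, day, parameter, mean, sd)."""
    rows = [
        {"group": g, "day": d, "parameter": p, "mean": m, "sd": s}
        for (g, d), params in MEASUREMENT_MOMENTS.items()
        for p, (m, s) in params.items()
    ]
    return pd.DataFrame(rows)


def index_table() -> pd.DataFrame:
    """All printed index moments as a tidy frame (group, day, index, mean, sd)."""
    rows = [
        {"group": g, "day": d, "index": i, "mean": m, "sd": s}
        for (g, d), idx in INDEX_MOMENTS.items()
        for i, (m, s) in idx.items()
    ]
    return pd.DataFrame(rows)
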