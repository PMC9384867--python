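"""Bundled reference tables for four holoparasitic plants and their hosts.

Published per-scenario summary values (habitat-class area percentages and
Schoener's D niche overlaps under a current climate plus four RCP/horizon
scenarios) for four parasite-host pairs in China. They serve as regression
fixtures for the area/typology arithmetic and the overlap statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SCENARIOS",
    "PAIRS",
    "load_area_table",
    "load_overlap_table",
    "species_roles",
]

SCENARIOS = (
    "current",
    "RCP2.6-2050s",
    "RCP8.5-2050s",
    "RCP2.6-2070s",
    "RCP8.5-2070s",
)

#: (parasite, host) pairs in study order.
PAIRS = (
    ("Cynomorium songaricum", "Nitraria sibirica"),
    ("Boschniakia rossica", "Alnus mandshurica"),
    ("Cistanche deserticola", "Haloxylon ammodendron"),
    ("Cistanche mongolica", "Tamarix ramosissima"),
)

# species -> scenario -> (pct_not, pct_low, pct_moderate, pct_high)
_AREA = {
    "Cynomorium songaricum": {
        "current": (91.35, 5.97, 2.13, 0.55),
        "RCP2.6-2050s": (91.69, 5.95, 1.93, 0.44),
        "RCP8.5-2050s": (91.71, 5.61, 2.24, 0.45),
        "RCP2.6-2070s": (91.65, 5.93, 2.01, 0.41),
        "RCP8.5-2070s": (90.89, 6.51, 2.16, 0.43),
    },
    "Nitraria sibirica": {
        "current": (65.91, 22.28, 10.81, 1.00),
        "RCP2.6-2050s": (62.21, 24.81, 11.94, 1.03),
        "RCP8.5-2050s": (61.96, 24.77, 12.30, 0.97),
        "RCP2.6-2070s": (62.58, 24.69, 11.54, 1.20),
        "RCP8.5-2070s": (62.78, 24.34, 11.74, 1.15),
    },
    "Boschniakia rossica": {
        "current": (88.62, 7.62, 2.96, 0.81),
        "RCP2.6-2050s": (87.99, 7.13, 3.99, 0.89),
        "RCP8.5-2050s": (88.48, 6.61, 3.96, 0.95),
        "RCP2.6-2070s": (88.54, 6.73, 3.62, 1.11),
        "RCP8.5-2070s": (88.52, 7.06, 3.28, 1.14),
    },
    "Alnus mandshurica": {
        "current": (95.05, 3.53, 1.24, 0.18),
        "RCP2.6-2050s": (95.14, 3.29, 1.47, 0.10),
        "RCP8.5-2050s": (94.53, 3.71, 1.66, 0.10),
        "RCP2.6-2070s": (94.83, 3.54, 1.43, 0.20),
        "RCP8.5-2070s": (94.49, 3.61, 1.73, 0.16),
    },
    "Cistanche deserticola": {
        "current": (91.01, 5.35, 3.27, 0.38),
        "RCP2.6-2050s": (90.58, 5.96, 3.04, 0.42),
        "RCP8.5-2050s": (90.56, 5.97, 3.14, 0.34),
        "RCP2.6-2070s": (90.35, 6.03, 3.34, 0.28),
        "RCP8.5-2070s": (90.26, 6.07, 3.40, 0.28),
    },
    "Haloxylon ammodendron": {
        "current": (83.11, 7.29, 9.31, 0.29),
        "RCP2.6-2050s": (79.78, 11.31, 8.41, 0.50),
        "RCP8.5-2050s": (79.48, 11.42, 8.86, 0.24),
        "RCP2.6-2070s": (79.65, 11.26, 8.69, 0.40),
        "RCP8.5-2070s": (80.28, 11.22, 7.41, 1.10),
    },
    "Cistanche mongolica": {
        "current": (97.33, 1.70, 0.78, 0.19),
        "RCP2.6-2050s": (95.59, 2.77, 1.51, 0.13),
        "RCP8.5-2050s": (95.31, 3.08, 1.52, 0.09),
        "RCP2.6-2070s": (95.67, 2.77, 1.48, 0.07),
        "RCP8.5-2070s": (95.32, 3.07, 1.53, 0.09),
    },
    "Tamarix ramosissima": {
        "current": (68.61, 17.96, 12.75, 0.68),
        "RCP2.6-2050s": (66.09, 19.74, 13.33, 0.83),
        "RCP8.5-2050s": (66.13, 20.15, 13.09, 0.63),
        "RCP2.6-2070s": (65.60, 20.11, 13.77, 0.52),
        "RCP8.5-2070s": (66.17, 20.71, 12.19, 0.93),
    },
}

# pair index (matching PAIRS) -> scenario -> Schoener's D
_OVERLAP = {
    0: {"current": 0.5180, "RCP2.6-2050s": 0.5238, "RCP8.5-2050s": 0.5080,
        "RCP2.6-2070s": 0.5115, "RCP8.5-2070s": 0.5096},
    1: {"current": 0.6673, "RCP2.6-2050s": 0.6769, "RCP8.5-2050s": 0.7067,
        "RCP2.6-2070s": 0.7208, "RCP8.5-2070s": 0.7316},
    2: {"current": 0.6585, "RCP2.6-2050s": 0.6684, "RCP8.5-2050s": 0.6577,
        "RCP2.6-2070s": 0.6792, "RCP8.5-2070s": 0.6746},
    3: {"current": 0.2593, "RCP2.6-2050s": 0.2908, "RCP8.5-2050s": 0.2853,
        "RCP2.6-2070s": 0.2846, "RCP8.5-2070s": 0.2723},
}

#: Distribution-shift trend labels reported for each species.
TREND_LABELS = {
    "Cynomorium songaricum": "fluctuating",
    "Nitraria sibirica": "growing",
    "Boschniakia rossica": "growing",
    "Alnus mandshurica": "growing",
    "Cistanche deserticola": "fluctuating",
    "Haloxylon ammodendron": "declining",
    "Cistanche mongolica": "growing",
    "Tamarix ramosissima": "fluctuating",
}

#: Overlap-shift trend labels reported for each pair (index into PAIRS).
OVERLAP_TREND_LABELS = {0: "fluctuating", 1: "growing", 2: "fluctuating", 3: "growing"}


def load_area_table() -> pd.DataFrame:
    """Long-format habitat-class area percentages per species and scenario."""
    rows = []
    for species, per_scenario in _AREA.items():
        for scenario, (p0, p1, p2, p3) in per_scenario.items():
            rows.append(
                {
                    "species": species,
                    "scenario": scenario,
                    "pct_not": p0,
                    "pct_low": p1,
                    "pct_moderate": p2,
                    "pct_high": p3,
                    "pct_suitable": round(p2 + p3, 2),
                }
            )
    return pd.DataFrame(rows)


def load_overlap_table() -> pd.DataFrame:
    """Long-format Schoener's D values per parasite-host pair and scenario."""
    rows = []
    for idx, per_scenario in _OVERLAP.items():
        parasite, host = PAIRS[idx]
        for scenario, d in per_scenario.items():
            rows.append(
                {"parasite": parasite, "host": host, "scenario": scenario, "D": d}
            )
    return pd.DataFrame(rows)


def species_roles() -> dict[str, str]:
    roles = {}
    for parasite, host in PAIRS:
        roles[parasite] = "parasite"
        roles[host] = "host"
    return roles
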