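"""Schoener's D niche overlap and cross-pair significance testing.

D(p_X, p_Y) = 1 - 0.5 * sum_i |p_X,i - p_Y,i| over suitability maps
normalized to probability distributions on their shared valid cells.
Group comparisons use classical one-way ANOVA plus the Tamhane T2 post-hoc
(Welch t per pair at a Sidak-adjusted per-comparison level) with a compact
letter display.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .maxent import SuitabilityMap
from .raster import Grid, intersect_mask

__all__ = [
    "OVERLAP_EDGES",
    "OVERLAP_NAMES",
    "OverlapResult",
    "GroupComparison",
    "schoener_d",
    "overlap_class",
    "pair_summary",
    "overlap_typology",
    "anova_oneway",
    "tamhane_t2",
]

#: Lower edges of the five overlap classes; top class closed at 1.
OVERLAP_EDGES = (0.0, 0.20, 0.40, 0.60, 0.80)
OVERLAP_NAMES = ("very_limited", "low", "moderate", "high", "very_high")


@dataclass
class OverlapResult:
    pair: tuple[str, str]                 # (parasite, host)
    per_scenario: dict[str, float]        # scenario -> D
    mean: float
    sd: float
    overlap_class_per_scenario: dict[str, str]
    typology: str


@dataclass
class GroupComparison:
    groups: dict[str, list[float]]
    F: float
    p: float
    pairwise: pd.DataFrame                # group_a, group_b, t, df, alpha_adj, significant
    letters: dict[str, str]


def schoener_d(map_x: SuitabilityMap | Grid, map_y: SuitabilityMap | Grid) -> float:
    """Schoener's D between two suitability maps on their shared valid cells."""
    gx = map_x.grid if isinstance(map_x, SuitabilityMap) else map_x
    gy = map_y.grid if isinstance(map_y, SuitabilityMap) else map_y
    mask = intersect_mask(gx, gy)
    if not mask.any():
        raise ValueError("maps share no valid cells")
    x = gx.values[mask]
    y = gy.values[mask]
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("overlap undefined: a map is all-zero on the shared cells")
    d = 1.0 - 0.5 * np.abs(x / sx - y / sy).sum()
    # guard tiny negative drift from float summation
    return float(min(1.0, max(0.0, d)))


def overlap_class(d: float) -> str:
    """Classify D on lower-closed bins (top bin closed at 1)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("Schoener's D must lie in [0, 1]")
    idx = int(np.clip(np.searchsorted(OVERLAP_EDGES, d, side="right"), 1, 5)) - 1
    return OVERLAP_NAMES[idx]


def pair_summary(per_scenario_d, ndigits: int = 4) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-scenario D values, rounded for report."""
    vals = np.asarray(
        list(per_scenario_d.values())
        if isinstance(per_scenario_d, dict)
        else per_scenario_d,
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("pair summary needs at least two scenario values")
    return (
        round(float(vals.mean()), ndigits),
        round(float(vals.std(ddof=1)), ndigits),
    )


def overlap_typology(current_d: float, future_ds) -> str:
    """Growing / declining / fluctuating rule on overlap values."""
    futures = list(future_ds)
    if all(f > current_d for f in futures):
        return "growing"
    if all(f < current_d for f in futures):
        return "declining"
    return "fluctuating"


# ---------------------------------------------------------------------------
# Group comparison

def anova_oneway(groups: dict[str, list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and its upper-tail p-value."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(v, float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2)  # equal-mean zero-variance convention
    t = abs(a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def _letter_display(names: list[str], means: dict[str, float],
                    nonsig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letters from maximal cliques of the non-significance graph."""
    # adjacency under non-significance (every group related to itself)
    adj = {n: {n} for n in names}
    for (a, b), ns in nonsig.items():
        if ns:
            adj[a].add(b)
            adj[b].add(a)

    # Bron-Kerbosch maximal cliques (tiny k; plain recursion is fine)
    cliques: list[frozenset[str]] = []

    def bk(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in list(p):
            nbr = adj[v] - {v}
            bk(r | {v}, p & nbr, x & nbr)
            p = p - {v}
            x = x | {v}

    bk(set(), set(names), set())
    cliques.sort(key=lambda c: (-max(means[g] for g in c), sorted(c)))
    letters = {n: "" for n in names}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for n in sorted(clique, key=lambda g: -means[g]):
            letters[n] += letter
    return letters


def tamhane_t2(groups: dict[str, list[float]], alpha: float = 0.01) -> GroupComparison:
    """Tamhane T2 pairwise comparisons with a compact letter display.

    Per pair: Welch t with Satterthwaite df; per-comparison level
    alpha' = 1 - (1 - alpha)^(1/m) over the m pairs (Sidak); a pair is
    significant iff t exceeds the two-sided critical value at alpha'.
    """
    F, p = anova_oneway(groups)
    names = list(groups)
    arrays = {n: np.asarray(v, float) for n, v in groups.items()}
    m = len(names) * (len(names) - 1) // 2
    alpha_adj = 1.0 - (1.0 - alpha) ** (1.0 / m)

    rows = []
    nonsig: dict[tuple[str, str], bool] = {}
    for a, b in combinations(names, 2):
        t, df = _welch(arrays[a], arrays[b])
        crit = stats.t.ppf(1.0 - alpha_adj / 2.0, df)
        sig = bool(t > crit)
        rows.append((a, b, t, df, alpha_adj, sig))
        nonsig[(a, b)] = not sig
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "t", "df", "alpha_adj", "significant"]
    )
    means = {n: float(arrays[n].mean()) for n in names}
    letters = _letter_display(names, means, nonsig)
    return GroupComparison(
        groups={n: list(map(float, arrays[n])) for n in names},
        F=F, p=p, pairwise=pairwise, letters=letters,
    )
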