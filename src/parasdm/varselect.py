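"""Pairwise-correlation variable reduction with contribution tie-breaking.

Highly collinear climate layers are pruned greedily: while any retained
pair correlates beyond the threshold (|r| > 0.7 by default), the pair with
the largest |r| is resolved by dropping its lower-contribution member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxent import fit as maxent_fit, variable_contribution
from .occurrences import SampleTable, concat_samples

__all__ = [
    "CorrelationReport",
    "SelectionResult",
    "pearson_matrix",
    "pilot_contributions",
    "select_variables",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    variables: list[str]
    r: np.ndarray               # symmetric, unit diagonal
    sample_basis: str = "presence+background"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class SelectionResult:
    retained: list[str]
    dropped: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (variable, against, |r|, contribution)
    contributions: dict[str, float] = field(default_factory=dict)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dropped, columns=["variable", "against", "abs_r", "contribution"]
        )


def pearson_matrix(
    samples: SampleTable | np.ndarray,
    variables: list[str] | None = None,
    basis: str = "presence+background",
) -> CorrelationReport:
    """Pearson correlation matrix over the chosen sample rows.

    Constant columns get r = 0 against every other variable (with a warning);
    the diagonal stays 1.
    """
    if isinstance(samples, SampleTable):
        variables = samples.variables
        if basis == "presence":
            x = samples.presence
        elif basis == "background":
            x = samples.background
        else:
            x = samples.values
    else:
        x = np.asarray(samples, dtype=float)
        if variables is None:
            variables = [f"v{i}" for i in range(x.shape[1])]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows to correlate")

    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        log.warning(
            "constant columns in correlation basis: %s",
            [v for v, c in zip(variables, constant) if c],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return CorrelationReport(variables=list(variables), r=r, sample_basis=basis)


def pilot_contributions(
    presences: SampleTable,
    background: SampleTable,
    fc: str = "LQ",
    rm: float = 1.0,
    **fit_kwargs,
) -> dict[str, float]:
    """Percent contribution per variable from an all-variables pilot model."""
    samples = concat_samples([presences, background])
    model = maxent_fit(samples, fc, rm, **fit_kwargs)
    contrib = variable_contribution(model, samples)
    return contrib.percent


def select_variables(
    report: CorrelationReport,
    contributions: dict[str, float],
    threshold: float = 0.7,
) -> SelectionResult:
    """Greedy elimination of correlated variable pairs.

    While any retained pair has |r| > threshold: take the pair with the
    largest |r| (ties broken lexicographically on the sorted name pair) and
    drop its lower-contribution member; if contributions tie, drop the
    alphabetically later name. Every drop is recorded.
    """
    names = list(report.variables)
    if set(names) != set(contributions):
        raise ValueError("contributions must cover exactly the correlated variables")
    idx = {v: i for i, v in enumerate(names)}
    retained = sorted(names)
    dropped: list[tuple[str, str, float, float]] = []

    while True:
        worst: tuple | None = None
        for a_i, a in enumerate(retained):
            for b in retained[a_i + 1:]:
                rv = abs(report.r[idx[a], idx[b]])
                if rv > threshold:
                    key = (-rv, a, b)
                    if worst is None or key < worst[0]:
                        worst = (key, a, b, rv)
        if worst is None:
            break
        _, a, b, rv = worst
        ca, cb = contributions[a], contributions[b]
        if ca < cb:
            victim, keeper = a, b
        elif cb < ca:
            victim, keeper = b, a
        else:  # equal contributions: drop the later alphabetical name
            victim, keeper = (b, a) if a < b else (a, b)
        retained.remove(victim)
        dropped.append((victim, keeper, rv, contributions[victim]))

    # report retained in original column order
    retained_ordered = [v for v in names if v in set(retained)]
    return SelectionResult(
        retained=retained_ordered, dropped=dropped, contributions=dict(contributions)
    )
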