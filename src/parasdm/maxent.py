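"""Presence-background maximum-entropy suitability model.

The model maximizes the L1-penalized presence log-likelihood

    J(beta) = mean_presence eta(x) - log sum_background exp(eta(x))
              - sum_j lambda_j |beta_j|

over feature transforms of the climate variables, where eta is linear in
the features. lambda_j = rm * r_class(m) * s_j / sqrt(m) with s_j the
feature's standard deviation over the m presences and r_class an
interpolated per-feature-class base rate (shipped table below). The
objective is concave; it is maximized by a proximal-Newton scheme: each
outer step builds the quadratic model of the log-partition term and solves
the L1-penalized model by cyclic coordinate descent with soft
thresholding (exact zeros), followed by an Armijo line search on the true
objective.

Outputs: raw (normalized over the training background, summing to 1) and
logistic suitability L = c*q / (1 + c*q) with c = exp(H), H the entropy of
the raw distribution. A null model therefore scores exactly 0.5 everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .occurrences import SampleTable
from .raster import Grid, RasterStack

__all__ = [
    "FeatureDef",
    "FeatureSpace",
    "MaxentModel",
    "SuitabilityMap",
    "ContributionReport",
    "ConvergenceError",
    "build_features",
    "build_feature_space",
    "fit",
    "predict_raw",
    "predict_logistic",
    "project",
    "variable_contribution",
    "DEFAULT_REG_TABLE",
    "FEATURE_CLASS_SETS",
]

log = logging.getLogger(__name__)

#: Feature-class combinations used for tuning, in canonical order.
FEATURE_CLASS_SETS = ("L", "H", "LQ", "LQH", "LQHP", "LQHPT")

#: Per-class base regularization rates, linearly interpolated in the number
#: of presences m and clamped at the table ends.
DEFAULT_REG_TABLE: dict[str, tuple[list[float], list[float]]] = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 1.0, 0.5, 0.1]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "threshold": ([0, 100], [2.0, 1.0]),
}

_KIND_TO_CLASS = {
    "linear": "linear",
    "quadratic": "quadratic",
    "product": "product",
    "hinge_forward": "hinge",
    "hinge_reverse": "hinge",
    "threshold": "threshold",
}


class ConvergenceError(RuntimeError):
    """Solver failed to reach tolerance; carries the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class FeatureDef:
    """One model covariate derived from raw climate variables."""

    kind: str                       # linear|quadratic|product|hinge_forward|hinge_reverse|threshold
    parents: tuple[str, ...]        # one variable; two (distinct) for product
    knot: float | None = None       # hinge/threshold breakpoint in raw units
    scale: tuple[float, float] | tuple[tuple[float, float], ...] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_TO_CLASS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "product":
            if len(self.parents) != 2 or self.parents[0] == self.parents[1]:
                raise ValueError("product features need two distinct parents")
        elif len(self.parents) != 1:
            raise ValueError(f"{self.kind} features take exactly one parent")

    @property
    def reg_class(self) -> str:
        return _KIND_TO_CLASS[self.kind]

    def label(self) -> str:
        if self.kind == "product":
            return f"product({self.parents[0]},{self.parents[1]})"
        if self.knot is not None:
            return f"{self.kind}({self.parents[0]}@{self.knot:g})"
        return f"{self.kind}({self.parents[0]})"


def _scaled(x: np.ndarray, scale: tuple[float, float]) -> np.ndarray:
    mn, mx = scale
    rng = mx - mn
    if rng <= 0:
        return np.zeros_like(x)
    return (x - mn) / rng


def evaluate_feature(feat: FeatureDef, columns: dict[str, np.ndarray]) -> np.ndarray:
    if feat.kind == "linear":
        return _scaled(columns[feat.parents[0]], feat.scale)  # type: ignore[arg-type]
    if feat.kind == "quadratic":
        return _scaled(columns[feat.parents[0]], feat.scale) ** 2  # type: ignore[arg-type]
    if feat.kind == "product":
        (sa, sb) = feat.scale  # type: ignore[misc]
        return _scaled(columns[feat.parents[0]], sa) * _scaled(columns[feat.parents[1]], sb)
    x = columns[feat.parents[0]]
    mn, mx = feat.scale  # type: ignore[misc]
    t = feat.knot
    if feat.kind == "hinge_forward":
        denom = mx - t if mx > t else 1.0
        return np.clip((x - t) / denom, 0.0, 1.0)
    if feat.kind == "hinge_reverse":
        denom = t - mn if t > mn else 1.0
        return np.clip((t - x) / denom, 0.0, 1.0)
    # threshold
    return (x > t).astype(float)


def feature_matrix(
    features: Sequence[FeatureDef], columns: dict[str, np.ndarray]
) -> np.ndarray:
    n = len(next(iter(columns.values())))
    out = np.empty((n, len(features)))
    for j, f in enumerate(features):
        out[:, j] = evaluate_feature(f, columns)
    return out


# ---------------------------------------------------------------------------
# Feature construction

def build_features(
    samples: SampleTable, fc_set: str, n_knots: int = 50
) -> list[FeatureDef]:
    """Construct feature definitions for a feature-class combination.

    Scales and knots come from the combined presence+background sample:
    linear/quadratic/product features are min-max scaled to [0,1]; hinge
    (forward and reverse) and threshold knots sit at up to ``n_knots``
    empirical quantiles strictly inside the training range. Features that
    are constant over the sample are dropped.
    """
    fc = fc_set.upper()
    bad = set(fc) - set("LQHPT")
    if bad:
        raise ValueError(f"unknown feature-class letters {sorted(bad)}")
    if samples.values.shape[0] == 0:
        raise ValueError("empty sample")
    cols = {v: samples.values[:, k] for k, v in enumerate(samples.variables)}
    scales = {v: (float(c.min()), float(c.max())) for v, c in cols.items()}
    variables = [v for v in samples.variables if scales[v][1] > scales[v][0]]
    dropped = set(samples.variables) - set(variables)
    if dropped:
        log.info("dropping constant variables from features: %s", sorted(dropped))

    feats: list[FeatureDef] = []
    if "L" in fc:
        feats += [FeatureDef("linear", (v,), scale=scales[v]) for v in variables]
    if "Q" in fc:
        feats += [FeatureDef("quadratic", (v,), scale=scales[v]) for v in variables]
    if "P" in fc:
        for a_i, a in enumerate(variables):
            for b in variables[a_i + 1:]:
                feats.append(
                    FeatureDef("product", (a, b), scale=(scales[a], scales[b]))
                )
    qs = np.arange(1, n_knots + 1) / (n_knots + 1)
    for v in variables:
        mn, mx = scales[v]
        knots = np.unique(np.quantile(cols[v], qs))
        knots = knots[(knots > mn) & (knots < mx)]
        if "H" in fc:
            for t in knots:
                feats.append(FeatureDef("hinge_forward", (v,), knot=float(t), scale=scales[v]))
                feats.append(FeatureDef("hinge_reverse", (v,), knot=float(t), scale=scales[v]))
        if "T" in fc:
            for t in knots:
                feats.append(FeatureDef("threshold", (v,), knot=float(t), scale=scales[v]))

    # drop features constant over the training sample
    keep: list[FeatureDef] = []
    for f in feats:
        col = evaluate_feature(f, cols)
        if col.max() > col.min():
            keep.append(f)
    return keep


@dataclass
class FeatureSpace:
    """Features plus their evaluated design matrix on a training sample."""

    features: list[FeatureDef]
    matrix: np.ndarray          # (n, J)
    samples: SampleTable
    training_range: dict[str, tuple[float, float]]

    @property
    def presence_rows(self) -> np.ndarray:
        return self.samples.label == 1

    def subset(self, keep: Sequence[int]) -> "FeatureSpace":
        keep = list(keep)
        return FeatureSpace(
            features=[self.features[j] for j in keep],
            matrix=self.matrix[:, keep],
            samples=self.samples,
            training_range=self.training_range,
        )


def build_feature_space(
    samples: SampleTable, fc_set: str, n_knots: int = 50
) -> FeatureSpace:
    feats = build_features(samples, fc_set, n_knots)
    cols = {v: samples.values[:, k] for k, v in enumerate(samples.variables)}
    training_range = {
        v: (float(c.min()), float(c.max())) for v, c in cols.items()
    }
    return FeatureSpace(
        features=feats,
        matrix=feature_matrix(feats, cols),
        samples=samples,
        training_range=training_range,
    )


# ---------------------------------------------------------------------------
# Model

@dataclass
class MaxentModel:
    features: list[FeatureDef]
    beta: np.ndarray
    rm: float
    fc: str
    variables: list[str]
    background_cells: np.ndarray
    logZ: float
    H: float
    training_range: dict[str, tuple[float, float]]
    lambdas: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_presence: int = 0
    objective_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        """Number of nonzero coefficients."""
        return int(np.count_nonzero(self.beta))

    def eta(self, columns: dict[str, np.ndarray], clamp: bool = False) -> np.ndarray:
        if clamp:
            columns = {
                v: np.clip(x, *self.training_range[v]) if v in self.training_range else x
                for v, x in columns.items()
            }
        fm = feature_matrix(self.features, columns)
        return fm @ self.beta

    def eta_from_matrix(self, fm: np.ndarray) -> np.ndarray:
        return fm @ self.beta


@dataclass
class SuitabilityMap:
    """Per-cell habitat suitability index in [0, 1] on valid cells."""

    grid: Grid
    species: str | None = None
    scenario: str | None = None
    statistic: str = "single"


# ---------------------------------------------------------------------------
# Fitting

def _interp_rate(reg_class: str, m: int, table) -> float:
    ms, vs = table[reg_class]
    return float(np.interp(m, ms, vs))


def compute_lambdas(
    space: FeatureSpace, rm: float, reg_table=None, s_floor: float = 1e-4
) -> np.ndarray:
    table = reg_table or DEFAULT_REG_TABLE
    pres = space.matrix[space.presence_rows]
    m = pres.shape[0]
    s = pres.std(axis=0)
    s = np.maximum(s, s_floor)
    rates = np.array([_interp_rate(f.reg_class, m, table) for f in space.features])
    return rm * rates * s / np.sqrt(m)


def _smooth_objective(beta, Fp_mean, Fb):
    eta_b = Fb @ beta
    return -float(Fp_mean @ beta) + float(logsumexp(eta_b))


def _smooth_grad(beta, Fp_mean, Fb):
    eta_b = Fb @ beta
    w = eta_b - eta_b.max()
    q = np.exp(w)
    q /= q.sum()
    return -Fp_mean + Fb.T @ q


def _prox_newton(
    Fp_mean: np.ndarray,
    Fb: np.ndarray,
    lam: np.ndarray,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
    max_sweeps: int = 100,
) -> tuple[np.ndarray, list[float], bool]:
    """Minimize -mean_p(eta) + logsumexp(eta_b) + sum lam|beta|.

    Outer proximal-Newton iterations; the inner L1-penalized quadratic
    model is solved by cyclic coordinate descent with an active-set
    strategy, then an Armijo backtracking step on the true objective.
    """
    N, J = Fb.shape

    def total(b: np.ndarray) -> float:
        return _smooth_objective(b, Fp_mean, Fb) + float(lam @ np.abs(b))

    f_cur = total(beta)
    trace = [f_cur]
    converged = False
    for _outer in range(max_iter):
        eta = Fb @ beta
        w = eta - eta.max()
        q = np.exp(w)
        q /= q.sum()
        g = -Fp_mean + Fb.T @ q                 # smooth gradient
        mu = q @ Fb                             # E_q[f_j]
        h = q @ (Fb * Fb) - mu * mu             # per-coordinate curvature
        h = np.maximum(h, 1e-9)

        delta = np.zeros(J)
        r = np.zeros(N)                         # Fb @ delta
        qr = 0.0                                # q @ r
        order = np.arange(J)
        active: np.ndarray | None = None
        sweep = 0
        while sweep < max_sweeps:
            idx = order if active is None else active
            max_step = 0.0
            qrvec = q * r
            for j in idx:
                col = Fb[:, j]
                hd_j = float(col @ qrvec) - mu[j] * qr      # (H delta)_j
                a = h[j]
                b_lin = g[j] + hd_j - a * delta[j]
                z = a * beta[j] - b_lin
                u_new = math.copysign(max(abs(z) - lam[j], 0.0), z) / a
                dd = (u_new - beta[j]) - delta[j]
                if dd != 0.0:
                    delta[j] += dd
                    r += col * dd
                    qr += mu[j] * dd
                    qrvec = q * r
                    max_step = max(max_step, abs(dd) * math.sqrt(a))
            sweep += 1
            if max_step < 1e-10:
                if active is None:
                    break
                active = None                    # full verification sweep
            else:
                nz = np.flatnonzero((beta + delta) != 0.0)
                active = nz if nz.size else None

        if not np.any(delta):
            converged = True
            break
        # Armijo backtracking on the penalized objective
        model_decrease = float(g @ delta) + float(
            lam @ (np.abs(beta + delta) - np.abs(beta))
        )
        step = 1.0
        accepted = False
        for _ls in range(40):
            cand = beta + step * delta
            f_new = total(cand)
            if f_new <= f_cur + 1e-4 * step * model_decrease or f_new < f_cur:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True                     # no further descent possible
            break
        beta = cand
        trace.append(f_new)
        if abs(f_cur - f_new) <= tol * (abs(f_new) + 1.0):
            f_cur = f_new
            converged = True
            break
        f_cur = f_new
    beta[np.abs(beta) < 1e-12] = 0.0
    return beta, trace, converged


def fit(
    samples: SampleTable | FeatureSpace,
    fc_set: str = "LQ",
    rm: float = 1.0,
    n_knots: int = 50,
    tol: float = 1e-9,
    max_iter: int = 200,
    beta0: np.ndarray | None = None,
    reg_table=None,
    on_no_convergence: str = "raise",
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    ``samples`` may be a SampleTable (features are built here) or a
    prebuilt FeatureSpace (for warm starts / shared tuning grids).
    """
    if isinstance(samples, FeatureSpace):
        space = samples
    else:
        space = build_feature_space(samples, fc_set, n_knots)
    st = space.samples
    pres = space.presence_rows
    m = int(pres.sum())
    nb = int((~pres).sum())
    if m < 1:
        raise ValueError("need at least one presence")
    if nb < 2:
        raise ValueError("need at least two background points")
    if not np.all(np.isfinite(space.matrix)):
        raise ValueError("non-finite feature values")

    Fp_mean = space.matrix[pres].mean(axis=0)
    Fb = space.matrix[~pres]
    lam = compute_lambdas(space, rm, reg_table)
    beta_init = (
        np.zeros(len(space.features)) if beta0 is None
        else np.asarray(beta0, float).copy()
    )
    beta, trace, converged = _prox_newton(Fp_mean, Fb, lam, beta_init, tol, max_iter)
    if not converged:
        msg = (
            f"maxent solver did not reach tol={tol} in {max_iter} outer "
            f"iterations (objective {trace[-1]:.8g})"
        )
        if on_no_convergence == "raise":
            raise ConvergenceError(msg, trace)
        log.warning(msg)

    eta_b = Fb @ beta
    logZ = float(logsumexp(eta_b))
    q = np.exp(eta_b - logZ)
    q /= q.sum()
    # H = -sum q ln q = logZ - sum q eta; this form is exact for the null model
    H = logZ - float(q @ eta_b)

    return MaxentModel(
        features=list(space.features),
        beta=beta,
        rm=rm,
        fc=fc_set,
        variables=list(st.variables),
        background_cells=st.cell[~pres].copy(),
        logZ=logZ,
        H=H,
        training_range=dict(space.training_range),
        lambdas=lam,
        n_presence=m,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Prediction

def _columns_from(stack_or_samples, variables) -> tuple[dict[str, np.ndarray], np.ndarray | None, Grid | None]:
    """Return per-variable flat columns, a valid mask (grids only), geometry."""
    if isinstance(stack_or_samples, RasterStack):
        geom = stack_or_samples.geometry
        cols = {}
        for v in variables:
            cols[v] = stack_or_samples[v].values.ravel()
        valid = np.all(
            np.stack([np.isfinite(cols[v]) for v in variables]), axis=0
        )
        # replace NaN so feature eval stays finite; masked out afterwards
        cols = {v: np.where(valid, c, 0.0) for v, c in cols.items()}
        return cols, valid, geom
    st: SampleTable = stack_or_samples
    cols = {v: st.values[:, k] for k, v in enumerate(st.variables)}
    return cols, None, None


def predict_raw(model: MaxentModel, stack_or_samples, clamp: bool = False):
    """Raw output exp(eta - logZ); sums to 1 over the training background.

    Returns a vector for SampleTable input, or a Grid for RasterStack input
    (NaN on nodata cells).
    """
    cols, valid, geom = _columns_from(stack_or_samples, model.variables)
    eta = model.eta(cols, clamp=clamp)
    with np.errstate(over="ignore"):        # extreme eta on toy instances
        q = np.exp(eta - model.logZ)
    if geom is None:
        return q
    q = np.where(valid, q, np.nan).reshape(geom.nrows, geom.ncols)
    return geom.copy(values=q)


def predict_logistic(model: MaxentModel, stack_or_samples, clamp: bool = False,
                     species: str | None = None, scenario: str | None = None):
    """Logistic habitat suitability L = c*q / (1 + c*q), c = exp(H)."""
    cols, valid, geom = _columns_from(stack_or_samples, model.variables)
    eta = model.eta(cols, clamp=clamp)
    # L = exp(H + eta - logZ) / (1 + exp(...)) computed stably
    u = model.H + eta - model.logZ
    L = np.where(u > 0, 1.0 / (1.0 + np.exp(-u)), np.exp(u) / (1.0 + np.exp(u)))
    if geom is None:
        return L
    L = np.where(valid, L, np.nan).reshape(geom.nrows, geom.ncols)
    return SuitabilityMap(grid=geom.copy(values=L), species=species, scenario=scenario)


def project(model: MaxentModel, new_stack: RasterStack, clamp: bool = True,
            species: str | None = None, scenario: str | None = None) -> SuitabilityMap:
    """Project the model onto a (possibly future) climate stack.

    With clamp=True (default) each variable is clipped to its training
    min/max before feature evaluation; nodata propagates.
    """
    return predict_logistic(model, new_stack, clamp=clamp,
                            species=species, scenario=scenario)


# ---------------------------------------------------------------------------
# Serialization

MODEL_SCHEMA_VERSION = 1


def save_model(model: MaxentModel, path) -> None:
    """Write the fitted model as a versioned JSON document."""
    import json

    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "fc": model.fc,
        "rm": model.rm,
        "variables": model.variables,
        "logZ": model.logZ,
        "H": model.H,
        "n_presence": model.n_presence,
        "training_range": {v: list(r) for v, r in model.training_range.items()},
        "background_cells": model.background_cells.tolist(),
        "features": [
            {
                "kind": f.kind,
                "parents": list(f.parents),
                "knot": f.knot,
                "scale": (
                    [list(s) for s in f.scale] if f.kind == "product"
                    else list(f.scale)
                ),
            }
            for f in model.features
        ],
        "beta": model.beta.tolist(),
        "lambdas": model.lambdas.tolist() if model.lambdas is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> MaxentModel:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    features = []
    for f in doc["features"]:
        scale = (
            tuple(tuple(s) for s in f["scale"]) if f["kind"] == "product"
            else tuple(f["scale"])
        )
        features.append(
            FeatureDef(f["kind"], tuple(f["parents"]), knot=f["knot"], scale=scale)
        )
    return MaxentModel(
        features=features,
        beta=np.asarray(doc["beta"], float),
        rm=doc["rm"],
        fc=doc["fc"],
        variables=list(doc["variables"]),
        background_cells=np.asarray(doc["background_cells"], int),
        logZ=doc["logZ"],
        H=doc["H"],
        training_range={v: tuple(r) for v, r in doc["training_range"].items()},
        lambdas=(None if doc["lambdas"] is None
                 else np.asarray(doc["lambdas"], float)),
        n_presence=doc["n_presence"],
    )


# ---------------------------------------------------------------------------
# Variable importance

@dataclass
class ContributionReport:
    percent: dict[str, float]           # leave-one-out gain shares, sums to 100
    gain_full: float
    gain_without: dict[str, float]      # jackknife: model without the variable
    gain_with_only: dict[str, float]    # jackknife: model with only the variable

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": list(self.percent),
                "percent_contribution": [self.percent[v] for v in self.percent],
                "gain_without": [self.gain_without[v] for v in self.percent],
                "gain_with_only": [self.gain_with_only[v] for v in self.percent],
            }
        )


def _penalized_gain(model: MaxentModel, space: FeatureSpace) -> float:
    pres = space.presence_rows
    Fp_mean = space.matrix[pres].mean(axis=0)
    Fb = space.matrix[~pres]
    f = _smooth_objective(model.beta, Fp_mean, Fb) + float(
        model.lambdas @ np.abs(model.beta)
    )
    null = np.log(Fb.shape[0])  # objective at beta = 0
    return null - f


def variable_contribution(
    model: MaxentModel,
    samples: SampleTable,
    reg_table=None,
) -> ContributionReport:
    """Leave-one-variable-out gain attribution, normalized to 100 percent.

    For each variable the model is refit without that variable's features
    (products touching it included); its contribution is the drop in
    penalized training gain, floored at zero. With-only gains are also
    reported for the jackknife panel.
    """
    space = FeatureSpace(
        features=list(model.features),
        matrix=feature_matrix(
            model.features,
            {v: samples.values[:, k] for k, v in enumerate(samples.variables)},
        ),
        samples=samples,
        training_range=dict(model.training_range),
    )
    gain_full = _penalized_gain(model, space)

    raw_contrib: dict[str, float] = {}
    gain_without: dict[str, float] = {}
    gain_with_only: dict[str, float] = {}
    for v in model.variables:
        without_idx = [
            j for j, f in enumerate(model.features) if v not in f.parents
        ]
        only_idx = [j for j, f in enumerate(model.features) if f.parents == (v,)]
        for label, idx, store in (
            ("without", without_idx, gain_without),
            ("with_only", only_idx, gain_with_only),
        ):
            if not idx:
                store[v] = 0.0
                continue
            sub = space.subset(idx)
            try:
                refit = fit(
                    sub, fc_set=model.fc, rm=model.rm,
                    beta0=model.beta[idx], reg_table=reg_table,
                    on_no_convergence="warn",
                )
                store[v] = _penalized_gain(refit, sub)
            except (ValueError, ConvergenceError) as exc:
                log.warning("refit %s %s failed: %s", label, v, exc)
                store[v] = np.nan
        raw_contrib[v] = max(0.0, gain_full - gain_without[v])

    total = sum(raw_contrib.values())
    if total <= 0:
        log.warning("all leave-one-out gains zero; splitting contribution uniformly")
        pct = {v: 100.0 / len(raw_contrib) for v in raw_contrib}
    else:
        pct = {v: 100.0 * c / total for v, c in raw_contrib.items()}
    return ContributionReport(
        percent=pct,
        gain_full=gain_full,
        gain_without=gain_without,
        gain_with_only=gain_with_only,
    )
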