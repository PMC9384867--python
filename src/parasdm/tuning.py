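"""Model tuning by AICc over an RM x FC grid, and replicate evaluation.

Candidate models are refit to all presences (no split) and ranked by the
small-sample AIC with the presence likelihood renormalized over every valid
study cell; evaluation uses independent 75/25 presence splits scored by AUC
and maximum TSS against the background sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent import (
    FEATURE_CLASS_SETS,
    ConvergenceError,
    MaxentModel,
    SuitabilityMap,
    build_feature_space,
    fit,
    predict_logistic,
)
from .occurrences import SampleTable, concat_samples
from .raster import RasterStack

__all__ = [
    "TuningResult",
    "EvalScore",
    "ReplicateEnsemble",
    "DEFAULT_RM_GRID",
    "aicc",
    "tune",
    "split_replicates",
    "auc",
    "tss",
    "evaluate",
    "fit_replicates",
    "aggregate",
]

log = logging.getLogger(__name__)

DEFAULT_RM_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class TuningResult:
    candidates: pd.DataFrame      # columns rm, fc, loglik, k, AICc, delta_AICc
    selected: tuple[float, str]   # (rm, fc) with delta_AICc == 0
    models: dict[tuple[float, str], MaxentModel] = field(default_factory=dict)

    @property
    def selected_model(self) -> MaxentModel:
        return self.models[self.selected]


@dataclass
class EvalScore:
    auc: float
    tss: float
    threshold_at_max_tss: float


@dataclass
class ReplicateEnsemble:
    replicates: list[MaxentModel]
    scores: list[EvalScore]
    mean_map: SuitabilityMap | None
    auc_mean: float
    auc_sd: float
    tss_mean: float
    tss_sd: float

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": range(1, len(self.scores) + 1),
                "auc": [s.auc for s in self.scores],
                "tss": [s.tss for s in self.scores],
                "threshold_at_max_tss": [s.threshold_at_max_tss for s in self.scores],
            }
        )


# ---------------------------------------------------------------------------
# Information criterion

def aicc(
    model: MaxentModel,
    presence_samples: SampleTable,
    study_samples: SampleTable,
) -> tuple[float, int, float]:
    """(loglik, k, AICc) with the raw output renormalized over the study cells.

    ``study_samples`` holds every valid study-region cell (or the fixed cell
    sample standing in for it); k counts nonzero coefficients. AICc is +inf
    when k >= n - 1.
    """
    cols_study = {
        v: study_samples.values[:, i] for i, v in enumerate(study_samples.variables)
    }
    eta_study = model.eta(cols_study)
    from scipy.special import logsumexp

    logZ_study = float(logsumexp(eta_study))
    cols_p = {
        v: presence_samples.values[:, i]
        for i, v in enumerate(presence_samples.variables)
    }
    eta_p = model.eta(cols_p)
    loglik = float(np.sum(eta_p - logZ_study))
    k = model.k
    n = presence_samples.values.shape[0]
    if n < 2:
        raise ValueError("AICc needs at least two presences")
    if k >= n - 1:
        return loglik, k, math.inf
    value = 2 * k - 2 * loglik + (2 * k * (k + 1)) / (n - k - 1)
    return loglik, k, value


# ---------------------------------------------------------------------------
# Tuning

def tune(
    samples: SampleTable,
    study_samples: SampleTable | None = None,
    rm_grid=DEFAULT_RM_GRID,
    fc_sets=FEATURE_CLASS_SETS,
    n_knots: int = 50,
    keep_models: bool = True,
    **fit_kwargs,
) -> TuningResult:
    """Fit every RM x FC candidate on all presences and select min AICc.

    Ties break by smaller k, then smaller rm, then fc order as listed.
    ``study_samples`` defaults to the background rows of ``samples``.
    """
    if study_samples is None:
        study_samples = SampleTable(
            variables=samples.variables,
            values=samples.background,
            label=np.zeros(len(samples.background), int),
            cell=samples.cell[samples.label == 0],
        )
    presence_samples = SampleTable(
        variables=samples.variables,
        values=samples.presence,
        label=np.ones(samples.n_presence, int),
        cell=samples.cell[samples.label == 1],
    )

    rows = []
    models: dict[tuple[float, str], MaxentModel] = {}
    for fc in fc_sets:
        space = build_feature_space(samples, fc, n_knots)
        beta0 = None
        for rm in sorted(rm_grid, reverse=True):  # warm-start from sparser fits
            try:
                model = fit(space, fc_set=fc, rm=rm, beta0=beta0, **fit_kwargs)
            except ConvergenceError as exc:
                log.warning("candidate rm=%s fc=%s failed: %s", rm, fc, exc)
                rows.append((rm, fc, np.nan, np.nan, math.inf))
                continue
            beta0 = model.beta
            loglik, k, value = aicc(model, presence_samples, study_samples)
            rows.append((rm, fc, loglik, k, value))
            if keep_models:
                models[(rm, fc)] = model

    table = pd.DataFrame(rows, columns=["rm", "fc", "loglik", "k", "AICc"])
    fc_order = {fc: i for i, fc in enumerate(fc_sets)}
    table["fc_order"] = table["fc"].map(fc_order)
    table = table.sort_values(["rm", "fc_order"]).reset_index(drop=True)
    if not np.isfinite(table["AICc"]).any():
        raise RuntimeError(
            "all tuning candidates have infinite AICc:\n" + table.to_string()
        )
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    ranked = table.sort_values(
        ["AICc", "k", "rm", "fc_order"], kind="mergesort"
    )
    best = ranked.iloc[0]
    table = table.drop(columns="fc_order")
    return TuningResult(
        candidates=table,
        selected=(float(best["rm"]), str(best["fc"])),
        models=models,
    )


# ---------------------------------------------------------------------------
# Replicate splits and scoring

def split_replicates(
    n_presence: int,
    frac: float = 0.75,
    n_rep: int = 15,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent uniform train/test splits of presence indices.

    Train size is ceil(frac * n); the remainder is the test set. A split
    leaving an empty test (or train) set is rejected.
    """
    rng = np.random.default_rng(rng)
    n_train = math.ceil(frac * n_presence)
    if n_train >= n_presence:
        raise ValueError(
            f"train fraction {frac} leaves no test presences (n={n_presence})"
        )
    if n_train < 1:
        raise ValueError("train fraction leaves no training presences")
    splits = []
    for _ in range(n_rep):
        perm = rng.permutation(n_presence)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        splits.append((train, test))
    return splits


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (rank formulation)."""
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("AUC needs scores in both groups")
    ranks = rankdata(np.concatenate([sp, sb]))
    r_p = ranks[: sp.size].sum()
    u = r_p - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def tss(scores_presence: np.ndarray, scores_background: np.ndarray) -> EvalScore:
    """Maximum TSS = sensitivity + specificity - 1 over observed thresholds.

    Sensitivity counts presences scoring >= t; specificity counts
    background scoring < t.
    """
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("TSS needs scores in both groups")
    thresholds = np.unique(np.concatenate([sp, sb]))
    sp_sorted = np.sort(sp)
    sb_sorted = np.sort(sb)
    # sensitivity(t) = frac(sp >= t), specificity(t) = frac(sb < t)
    sens = 1.0 - np.searchsorted(sp_sorted, thresholds, side="left") / sp.size
    spec = np.searchsorted(sb_sorted, thresholds, side="left") / sb.size
    vals = sens + spec - 1.0
    best = int(np.argmax(vals))
    a = auc(sp, sb)
    return EvalScore(auc=a, tss=float(vals[best]),
                     threshold_at_max_tss=float(thresholds[best]))


def evaluate(
    model: MaxentModel,
    test_presences: SampleTable,
    background: SampleTable,
) -> EvalScore:
    """AUC and max-TSS of logistic scores for held-out presences."""
    sp = predict_logistic(model, test_presences)
    sb = predict_logistic(model, background)
    return tss(sp, sb)


# ---------------------------------------------------------------------------
# Replicates

def fit_replicates(
    presences: SampleTable,
    background: SampleTable,
    fc: str,
    rm: float,
    stack: RasterStack | None = None,
    n_rep: int = 15,
    frac: float = 0.75,
    rng: np.random.Generator | int | None = None,
    n_knots: int = 50,
    species: str | None = None,
    scenario: str | None = None,
    **fit_kwargs,
) -> ReplicateEnsemble:
    """Train/test replicate models at the selected (rm, fc); aggregate maps."""
    rng = np.random.default_rng(rng)
    splits = split_replicates(presences.values.shape[0], frac, n_rep, rng)
    models, scores, maps = [], [], []
    for train_idx, test_idx in splits:
        train = SampleTable(
            variables=presences.variables,
            values=presences.values[train_idx],
            label=np.ones(len(train_idx), int),
            cell=presences.cell[train_idx],
        )
        test = SampleTable(
            variables=presences.variables,
            values=presences.values[test_idx],
            label=np.ones(len(test_idx), int),
            cell=presences.cell[test_idx],
        )
        samples = concat_samples([train, background])
        model = fit(samples, fc_set=fc, rm=rm, n_knots=n_knots,
                    on_no_convergence="warn", **fit_kwargs)
        models.append(model)
        scores.append(evaluate(model, test, background))
        if stack is not None:
            maps.append(predict_logistic(model, stack, clamp=True,
                                         species=species, scenario=scenario))
    ensemble = aggregate(models, scores, maps, species=species, scenario=scenario)
    return ensemble


def aggregate(
    models: list[MaxentModel],
    scores: list[EvalScore],
    maps: list[SuitabilityMap] | None = None,
    species: str | None = None,
    scenario: str | None = None,
) -> ReplicateEnsemble:
    """Cellwise mean of replicate logistic maps; mean/SD of AUC and TSS."""
    mean_map = None
    if maps:
        arr = np.stack([m.grid.values for m in maps])
        with np.errstate(invalid="ignore"):
            mean_vals = np.nanmean(arr, axis=0)
        mean_map = SuitabilityMap(
            grid=maps[0].grid.copy(values=mean_vals),
            species=species, scenario=scenario, statistic="replicate_mean",
        )
    aucs = np.array([s.auc for s in scores])
    tsss = np.array([s.tss for s in scores])
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return ReplicateEnsemble(
        replicates=models,
        scores=scores,
        mean_map=mean_map,
        auc_mean=float(aucs.mean()),
        auc_sd=sd(aucs),
        tss_mean=float(tsss.mean()),
        tss_sd=sd(tsss),
    )
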