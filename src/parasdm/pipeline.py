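"""End-to-end orchestration: per-species runs, parasite-host pairs, study.

Stage order per species: rarefy -> ensemble futures -> correlation filter
-> tune (RM x FC by AICc) -> replicate fits -> evaluate -> project all
scenarios -> classify -> area summaries -> trend typology. Key climate
factors are the variables whose percent contribution exceeds the
configured threshold (10% by default). Pair runs add per-scenario
Schoener's D, overlap classes, mean +/- SD, typology and the common
key-factor set; the study run adds a cross-pair ANOVA + Tamhane report.

All stage outputs are pure functions of (inputs, config, master seed);
per-stage generators are derived by stable hashing so stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import habitat, overlap, synth, tuning, varselect
from .maxent import (
    FEATURE_CLASS_SETS,
    MaxentModel,
    SuitabilityMap,
    predict_logistic,
    variable_contribution,
)
from .occurrences import (
    OccurrenceSet,
    SampleTable,
    concat_samples,
    extract_values,
    read_all_occurrences,
    sample_background,
    spatial_rarefy,
)
from .raster import (
    Grid,
    RasterStack,
    ensemble_mean,
    intersect_mask,
    read_ascii_grid,
    read_stack,
    write_ascii_grid,
)

__all__ = [
    "RunConfig",
    "StudyData",
    "SpeciesResult",
    "PairResult",
    "StageError",
    "load_study",
    "synthetic_study",
    "run_species",
    "run_pair",
    "run_study",
]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage, keeps partial artifacts."""

    def __init__(self, stage: str, species: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for {species!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All study settings, with published defaults."""

    indir: str | None = None          # directory holding manifest.json
    outdir: str = "results"
    corr_threshold: float = 0.7
    key_factor_threshold: float = 10.0
    rm_grid: tuple = tuning.DEFAULT_RM_GRID
    fc_sets: tuple = FEATURE_CLASS_SETS
    n_background: int = 10000
    n_replicates: int = 15
    train_fraction: float = 0.75
    n_knots: int = 50
    pilot_fc: str = "LQ"
    pilot_rm: float = 1.0
    alpha: float = 0.01
    latitude_weighted: bool = False
    master_seed: int = 0
    pairs: tuple = ()                 # ((parasite, host), ...)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        for key in ("rm_grid", "fc_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_rng(cfg: RunConfig, stage: str, species: str = "") -> np.random.Generator:
    digest = hashlib.sha256(
        f"{cfg.master_seed}:{stage}:{species}".encode()
    ).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} master_seed={cfg.master_seed}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Inputs

@dataclass
class StudyData:
    """Loaded study inputs: ensembled scenario stacks, mask, occurrences."""

    scenarios: dict[str, RasterStack]       # includes "current"
    mask: np.ndarray
    mask_template: Grid
    occurrences: dict[str, OccurrenceSet]

    @property
    def current(self) -> RasterStack:
        return self.scenarios["current"]

    @property
    def future_names(self) -> list[str]:
        return [s for s in self.scenarios if s != "current"]


def load_study(indir: str | Path) -> StudyData:
    """Load a study directory written by ``synth.write_study`` (or by hand).

    The manifest's scenario entries map variable -> path for a single
    member, or give a list of such mappings for multi-GCM scenarios, which
    are ensemble-averaged with equal weights here.
    """
    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    scenarios: dict[str, RasterStack] = {}
    for name, entry in manifest["scenarios"].items():
        if isinstance(entry, list):
            members = [
                read_stack({v: indir / p for v, p in member.items()})
                for member in entry
            ]
            scenarios[name] = ensemble_mean(members)
        else:
            scenarios[name] = read_stack({v: indir / p for v, p in entry.items()})
    if "current" not in scenarios:
        raise ValueError("manifest must define a 'current' scenario")

    mask_key = manifest.get("mask")
    if mask_key is None:
        raise FileNotFoundError("manifest has no mask entry")
    mask_path = indir / mask_key
    if not mask_path.exists():
        raise FileNotFoundError(f"mask file missing: {mask_path}")
    mask_grid = read_ascii_grid(mask_path)
    mask = mask_grid.valid & (mask_grid.values > 0)
    mask &= intersect_mask(*scenarios.values())

    occurrences = read_all_occurrences(indir / manifest["occurrences"])
    return StudyData(
        scenarios=scenarios,
        mask=mask,
        mask_template=mask_grid,
        occurrences=occurrences,
    )


def synthetic_study(
    nrows: int = 100,
    ncols: int = 100,
    K: int = 8,
    n_presence: int = 200,
    pairs: int = 1,
    offset_delta: float = 1.0,
    range_len: float = 5.0,
    seed: int = 0,
    warming_deltas: dict[str, float] | None = None,
) -> tuple[StudyData, dict[str, synth.SyntheticTruth]]:
    """Build an in-memory synthetic study with known truth.

    Creates ``pairs`` parasite-host pairs (species named parasite1/host1,
    ...), one current stack, and four future scenarios of increasing
    perturbation strength.
    """
    rng = np.random.default_rng(seed)
    cross = np.eye(K)
    # moderate cross-correlation between neighbouring layers
    for i in range(K - 1):
        cross[i, i + 1] = cross[i + 1, i] = 0.3
    stack = synth.gen_climate_stack(
        (nrows, ncols), K=K, range_len=range_len, cross_corr=cross, seed=rng
    )
    if warming_deltas is None:
        warming_deltas = {
            "RCP2.6-2050s": 10.0,
            "RCP8.5-2050s": 25.0,
            "RCP2.6-2070s": 15.0,
            "RCP8.5-2070s": 40.0,
        }
    scenarios: dict[str, RasterStack] = {"current": stack}
    for name, delta in warming_deltas.items():
        scenarios[name] = synth.gen_future(
            stack, warming_delta=delta, precip_scale=1.0 + delta / 200.0,
            field_sd=3.0, range_len=range_len, rng=rng,
        )

    truths: dict[str, synth.SyntheticTruth] = {}
    occurrences: dict[str, OccurrenceSet] = {}
    pair_list = []
    for p in range(pairs):
        vars_for_pair = [stack.variables[(2 * p) % K], stack.variables[(2 * p + 1) % K]]
        parasite, host = synth.gen_pair(
            stack, offset_delta=offset_delta, variables=vars_for_pair
        )
        pname, hname = f"parasite{p + 1}", f"host{p + 1}"
        parasite.species, host.species = pname, hname
        truths[pname], truths[hname] = parasite, host
        occurrences[pname] = synth.sample_presences(parasite, n_presence, rng=rng)
        occurrences[hname] = synth.sample_presences(host, n_presence, rng=rng)
        pair_list.append((pname, hname))

    geom = stack.geometry
    mask_grid = geom.copy(values=np.ones((nrows, ncols)))
    data = StudyData(
        scenarios=scenarios,
        mask=np.ones((nrows, ncols), bool),
        mask_template=mask_grid,
        occurrences=occurrences,
    )
    return data, truths


# ---------------------------------------------------------------------------
# Species run

@dataclass
class SpeciesResult:
    species: str
    retained_variables: list[str]
    selection: varselect.SelectionResult
    tuning: tuning.TuningResult
    ensemble: tuning.ReplicateEnsemble
    mean_maps: dict[str, SuitabilityMap]
    eval_table: pd.DataFrame
    contributions: dict[str, float]
    key_factors: list[str]
    area_summaries: dict[str, habitat.AreaSummary]
    typology: habitat.TrendTypology
    presences: SampleTable = None  # type: ignore[assignment]


def _eval_on_scenario(
    models: list[MaxentModel],
    maps: list[SuitabilityMap],
    test_cells_per_rep: list[np.ndarray],
    background_cells: np.ndarray,
) -> tuple[float, float]:
    """Mean AUC/TSS of replicate maps scored at held-out presence cells."""
    aucs, tsss = [], []
    for m, sm, test_cells in zip(models, maps, test_cells_per_rep):
        flat = sm.grid.values.ravel()
        sp = flat[test_cells]
        sb = flat[background_cells]
        sp = sp[np.isfinite(sp)]
        sb = sb[np.isfinite(sb)]
        score = tuning.tss(sp, sb)
        aucs.append(score.auc)
        tsss.append(score.tss)
    return float(np.mean(aucs)), float(np.mean(tsss))


def run_species(
    config: RunConfig,
    species: str,
    data: StudyData,
    outdir: Path | None = None,
) -> SpeciesResult:
    """Run the full per-species analysis; write Table-1/2/3 analogue CSVs."""
    cfg = config
    out = Path(outdir) if outdir is not None else Path(cfg.outdir) / species.replace(" ", "_")
    out.mkdir(parents=True, exist_ok=True)
    current = data.current
    stage = "rarefy"
    try:
        occ = data.occurrences[species]
        occ = spatial_rarefy(occ, current.geometry)

        stage = "extract"
        presences_full = extract_values(current, occ, label=1)
        background_full = sample_background(
            current, data.mask, cfg.n_background,
            _stage_rng(cfg, "background", species),
        )

        stage = "variable_selection"
        samples_full = concat_samples([presences_full, background_full])
        report = varselect.pearson_matrix(samples_full)
        contributions_pilot = varselect.pilot_contributions(
            presences_full, background_full,
            fc=cfg.pilot_fc, rm=cfg.pilot_rm, n_knots=cfg.n_knots,
            on_no_convergence="warn",
        )
        selection = varselect.select_variables(
            report, contributions_pilot, cfg.corr_threshold
        )
        retained = selection.retained
        scenarios = {n: s.subset(retained) for n, s in data.scenarios.items()}
        keep_idx = [samples_full.variables.index(v) for v in retained]
        presences = SampleTable(
            variables=retained,
            values=presences_full.values[:, keep_idx],
            label=presences_full.label,
            cell=presences_full.cell,
        )
        background = SampleTable(
            variables=retained,
            values=background_full.values[:, keep_idx],
            label=background_full.label,
            cell=background_full.cell,
        )

        stage = "tune"
        samples = concat_samples([presences, background])
        tune_result = tuning.tune(
            samples,
            rm_grid=cfg.rm_grid,
            fc_sets=cfg.fc_sets,
            n_knots=cfg.n_knots,
            on_no_convergence="warn",
        )
        rm_sel, fc_sel = tune_result.selected

        stage = "replicates"
        rng = _stage_rng(cfg, "replicates", species)
        splits = tuning.split_replicates(
            presences.values.shape[0], cfg.train_fraction, cfg.n_replicates, rng
        )
        models, scores, test_cells_per_rep = [], [], []
        for train_idx, test_idx in splits:
            train = SampleTable(
                variables=retained,
                values=presences.values[train_idx],
                label=np.ones(len(train_idx), int),
                cell=presences.cell[train_idx],
            )
            test = SampleTable(
                variables=retained,
                values=presences.values[test_idx],
                label=np.ones(len(test_idx), int),
                cell=presences.cell[test_idx],
            )
            model = tuning.fit(
                concat_samples([train, background]),
                fc_set=fc_sel, rm=rm_sel, n_knots=cfg.n_knots,
                on_no_convergence="warn",
            )
            models.append(model)
            scores.append(tuning.evaluate(model, test, background))
            test_cells_per_rep.append(test.cell)

        stage = "project"
        mean_maps: dict[str, SuitabilityMap] = {}
        eval_rows = []
        for name, sc_stack in scenarios.items():
            rep_maps = [
                predict_logistic(m, sc_stack, clamp=True,
                                 species=species, scenario=name)
                for m in models
            ]
            ens = tuning.aggregate(models, scores, rep_maps,
                                   species=species, scenario=name)
            mean_maps[name] = ens.mean_map
            auc_m, tss_m = _eval_on_scenario(
                models, rep_maps, test_cells_per_rep, background.cell
            )
            eval_rows.append(
                {"scenario": name, "auc_mean": round(auc_m, 3),
                 "tss_mean": round(tss_m, 3)}
            )
        ensemble = tuning.aggregate(
            models, scores,
            [predict_logistic(m, current, clamp=True, species=species,
                              scenario="current") for m in models],
            species=species, scenario="current",
        )
        eval_table = pd.DataFrame(eval_rows)

        stage = "contribution"
        selected_model = tune_result.selected_model
        contrib = variable_contribution(selected_model, samples)
        key_factors = sorted(
            [v for v, pct in contrib.percent.items()
             if pct > cfg.key_factor_threshold]
        )

        stage = "classify"
        area_summaries: dict[str, habitat.AreaSummary] = {}
        for name, sm in mean_maps.items():
            cls = habitat.classify(sm)
            write_ascii_grid(cls, out / f"class_{name}.asc", precision=1)
            write_ascii_grid(sm.grid, out / f"hsi_{name}.asc", precision=6)
            area_summaries[name] = habitat.area_summary(
                cls, data.mask, scenario=name,
                latitude_weighted=cfg.latitude_weighted,
            )

        stage = "typology"
        current_pct = area_summaries["current"].pct_suitable
        future_pcts = [area_summaries[n].pct_suitable for n in data.future_names]
        typology = habitat.trend_typology(current_pct, future_pcts)

        stage = "write"
        _write_csv(tune_result.candidates, out / "tuning.csv", cfg)
        _write_csv(eval_table, out / "evaluation.csv", cfg)
        contrib_df = contrib.to_frame()
        contrib_df["key_factor"] = contrib_df["variable"].isin(key_factors)
        _write_csv(contrib_df, out / "contributions.csv", cfg)
        area_df = habitat.area_table(list(area_summaries.values()))
        area_df["species"] = species
        area_df["typology"] = typology.label
        _write_csv(area_df, out / "area_dynamics.csv", cfg)
        corr_df = report.to_frame().reset_index(names="variable")
        _write_csv(corr_df, out / "correlation.csv", cfg)
        _write_csv(selection.audit_frame(), out / "selection_audit.csv", cfg)
        with open(out / "run_log.json", "w") as fh:
            json.dump(
                {
                    "species": species,
                    "config_hash": cfg.hash(),
                    "master_seed": cfg.master_seed,
                    "retained_variables": retained,
                    "selected_rm": rm_sel,
                    "selected_fc": fc_sel,
                    "n_presence": int(presences.values.shape[0]),
                    "n_background": int(background.values.shape[0]),
                    "auc_mean": ensemble.auc_mean,
                    "tss_mean": ensemble.tss_mean,
                    "key_factors": key_factors,
                    "typology": typology.label,
                },
                fh, indent=2, sort_keys=True,
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, species, exc) from exc

    return SpeciesResult(
        species=species,
        retained_variables=retained,
        selection=selection,
        tuning=tune_result,
        ensemble=ensemble,
        mean_maps=mean_maps,
        eval_table=eval_table,
        contributions=contrib.percent,
        key_factors=key_factors,
        area_summaries=area_summaries,
        typology=typology,
        presences=presences,
    )


# ---------------------------------------------------------------------------
# Pair and study runs

@dataclass
class PairResult:
    parasite: str
    host: str
    overlap: overlap.OverlapResult
    common_key_factors: list[str]


def run_pair(
    config: RunConfig,
    parasite: SpeciesResult,
    host: SpeciesResult,
    data: StudyData,
    outdir: Path | None = None,
) -> PairResult:
    """Schoener's D per scenario for a parasite-host pair, plus summaries."""
    cfg = config
    out = Path(outdir) if outdir is not None else (
        Path(cfg.outdir) / f"pair_{parasite.species}_{host.species}".replace(" ", "_")
    )
    out.mkdir(parents=True, exist_ok=True)

    per_scenario: dict[str, float] = {}
    classes: dict[str, str] = {}
    for name in data.scenarios:
        d = overlap.schoener_d(parasite.mean_maps[name], host.mean_maps[name])
        per_scenario[name] = d
        classes[name] = overlap.overlap_class(d)
    mean, sd = overlap.pair_summary(per_scenario)
    typ = overlap.overlap_typology(
        per_scenario["current"],
        [per_scenario[n] for n in data.future_names],
    )
    result = overlap.OverlapResult(
        pair=(parasite.species, host.species),
        per_scenario=per_scenario,
        mean=mean,
        sd=sd,
        overlap_class_per_scenario=classes,
        typology=typ,
    )
    common = sorted(set(parasite.key_factors) & set(host.key_factors))

    df = pd.DataFrame(
        {
            "scenario": list(per_scenario),
            "D": list(per_scenario.values()),
            "overlap_class": [classes[s] for s in per_scenario],
        }
    )
    df["parasite"] = parasite.species
    df["host"] = host.species
    df["mean"] = mean
    df["sd"] = sd
    df["typology"] = typ
    df["common_key_factors"] = ";".join(common)
    _write_csv(df, out / "overlap.csv", cfg)
    return PairResult(
        parasite=parasite.species, host=host.species,
        overlap=result, common_key_factors=common,
    )


def run_study(
    config: RunConfig,
    data: StudyData | None = None,
) -> dict:
    """All species, all pairs, plus the cross-pair ANOVA/Tamhane report."""
    cfg = config
    if data is None:
        if cfg.indir is None:
            raise ValueError("config.indir is required when no StudyData is given")
        data = load_study(cfg.indir)
    pairs = cfg.pairs or ()
    if not pairs:
        # default: every species on its own, no pairs
        species_list = list(data.occurrences)
    else:
        species_list = [s for pair in pairs for s in pair]

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    species_results: dict[str, SpeciesResult] = {}
    for sp in species_list:
        log.info("running species %s", sp)
        species_results[sp] = run_species(cfg, sp, data)

    pair_results: list[PairResult] = []
    for parasite, host in pairs:
        pair_results.append(
            run_pair(cfg, species_results[parasite], species_results[host], data)
        )

    report: dict = {
        "species": {s: r.typology.label for s, r in species_results.items()},
        "pairs": {
            f"{p.parasite}|{p.host}": {
                "mean": p.overlap.mean,
                "sd": p.overlap.sd,
                "typology": p.overlap.typology,
                "common_key_factors": p.common_key_factors,
            }
            for p in pair_results
        },
    }
    if len(pair_results) >= 2:
        groups = {
            f"{p.parasite}|{p.host}": list(p.overlap.per_scenario.values())
            for p in pair_results
        }
        comparison = overlap.tamhane_t2(groups, alpha=cfg.alpha)
        _write_csv(comparison.pairwise, out / "tamhane.csv", cfg)
        letters_df = pd.DataFrame(
            {
                "pair": list(comparison.letters),
                "letters": list(comparison.letters.values()),
                "mean": [np.mean(groups[g]) for g in comparison.letters],
            }
        )
        letters_df["F"] = comparison.F
        letters_df["p"] = comparison.p
        _write_csv(letters_df, out / "anova_letters.csv", cfg)
        report["anova"] = {"F": comparison.F, "p": comparison.p,
                           "letters": comparison.letters}

    with open(out / "study_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
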