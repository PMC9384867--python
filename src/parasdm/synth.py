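"""Synthetic study inputs: correlated climate fields, species with known
suitability truth, presence samples, future perturbations, parasite-host
pairs with a tunable niche offset.

Climate layers are Gaussian random fields built by kernel-smoothing white
noise, mixed through a Cholesky factor of the target cross-correlation and
affinely rescaled into temperature-like and precipitation-like ranges.
Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import Grid, RasterStack, write_ascii_grid, write_stack

__all__ = [
    "SyntheticTruth",
    "gen_climate_stack",
    "gen_species",
    "sample_presences",
    "gen_future",
    "gen_pair",
    "truth_schoener_d",
    "write_study",
]


@dataclass
class SyntheticTruth:
    """Known suitability truth for one simulated species."""

    species: str
    eta_true: Grid                      # linear predictor per cell
    responses: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def suitability(self) -> Grid:
        """exp(eta) normalized to sum 1 over valid cells."""
        eta = self.eta_true.values
        valid = np.isfinite(eta)
        z = np.full(eta.shape, np.nan)
        e = np.exp(eta[valid] - np.nanmax(eta))
        z[valid] = e / e.sum()
        return self.eta_true.copy(values=z)


def _smooth_unit_field(shape, range_len: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=range_len, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def gen_climate_stack(
    geometry: Grid | tuple[int, int] = (100, 100),
    K: int = 8,
    range_len: float = 5.0,
    cross_corr: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> RasterStack:
    """Generate K autocorrelated, cross-correlated climate layers.

    The first ceil(K/2) layers are temperature-like (degrees C x 10, may be
    negative); the rest precipitation-like (nonnegative mm). Pairwise cell
    correlations track ``cross_corr`` (default: identity).
    """
    rng = np.random.default_rng(seed)
    if isinstance(geometry, Grid):
        template = geometry
    else:
        nrows, ncols = geometry
        template = Grid(nrows=nrows, ncols=ncols, xll=100.0, yll=30.0,
                        cellsize=0.05, values=np.zeros((nrows, ncols)))
    shape = (template.nrows, template.ncols)
    if cross_corr is None:
        cross_corr = np.eye(K)
    cross_corr = np.asarray(cross_corr, float)
    if cross_corr.shape != (K, K) or not np.allclose(cross_corr, cross_corr.T):
        raise ValueError("cross_corr must be a symmetric K x K matrix")
    try:
        L = np.linalg.cholesky(cross_corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("cross_corr must be positive definite") from exc

    fields = np.stack([_smooth_unit_field(shape, range_len, rng) for _ in range(K)])
    mixed = np.einsum("kl,lij->kij", L, fields)

    n_temp = (K + 1) // 2
    layers: dict[str, Grid] = {}
    for k in range(K):
        f = mixed[k]
        if k < n_temp:
            vals = 100.0 + 60.0 * f        # temperature-like, tenths of a degree
        else:
            vals = np.maximum(0.0, 400.0 + 250.0 * f)  # precipitation-like, mm
        layers[f"Bio{k + 1}"] = template.copy(values=vals)
    return RasterStack(layers)


def _response_eta(stack: RasterStack, responses: list[dict]) -> np.ndarray:
    """Sum of linear / quadratic / hinge transforms of chosen layers."""
    geom = stack.geometry
    eta = np.zeros((geom.nrows, geom.ncols))
    for r in responses:
        x = stack[r["variable"]].values
        mu, sd = np.nanmean(x), np.nanstd(x)
        z = (x - mu) / (sd if sd > 0 else 1.0)
        kind = r.get("kind", "linear")
        w = r.get("weight", 1.0)
        if kind == "linear":
            eta = eta + w * z
        elif kind == "quadratic":
            opt = r.get("optimum", 0.0)
            width = r.get("width", 1.0)
            eta = eta - w * ((z - opt) / width) ** 2
        elif kind == "hinge":
            knot = r.get("knot", 0.0)
            eta = eta + w * np.maximum(0.0, z - knot)
        else:
            raise ValueError(f"unknown response kind {kind!r}")
    return eta


def gen_species(
    stack: RasterStack,
    response_spec: list[dict],
    species: str = "synthetic",
    seed: int | None = None,
) -> SyntheticTruth:
    """Build a species truth surface from a list of response terms.

    Each term: {variable, kind: linear|quadratic|hinge, weight, and for
    quadratic an optimum/width in standardized layer units, for hinge a knot}.
    """
    eta = _response_eta(stack, response_spec)
    geom = stack.geometry
    return SyntheticTruth(
        species=species,
        eta_true=geom.copy(values=eta),
        responses=[dict(r) for r in response_spec],
        seed=seed,
    )


def sample_presences(
    truth: SyntheticTruth,
    n: int,
    bias: Grid | None = None,
    rng: np.random.Generator | int | None = None,
) -> OccurrenceSet:
    """Draw n presence points with probability proportional to suitability.

    One coordinate is jittered uniformly within each drawn cell.
    """
    if n <= 0:
        raise ValueError("need n >= 1 presences")
    rng = np.random.default_rng(rng)
    suit = truth.suitability.values.copy()
    if bias is not None:
        suit = suit * bias.values
    flat = suit.ravel()
    valid = np.isfinite(flat) & (flat > 0)
    p = np.where(valid, flat, 0.0)
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability surface has no positive mass")
    p = p / total
    geom = truth.eta_true
    cells = rng.choice(flat.size, size=n, replace=True, p=p)
    i = cells // geom.ncols
    j = cells % geom.ncols
    u = rng.uniform(0.0, 1.0, size=(n, 2))
    lon = geom.xll + (j + u[:, 0]) * geom.cellsize
    lat = geom.yll + (geom.nrows - 1 - i + u[:, 1]) * geom.cellsize
    return OccurrenceSet(
        species=truth.species,
        records=np.column_stack([lon, lat]),
        provenance=["synthetic"],
    )


def gen_future(
    stack: RasterStack,
    warming_delta: float = 20.0,
    precip_scale: float = 1.1,
    field_sd: float = 5.0,
    range_len: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> RasterStack:
    """Perturb a stack into a future scenario.

    Temperature-like layers (names Bio1..Bio{ceil(K/2)}) shift by
    ``warming_delta`` plus a smooth random field of SD ``field_sd``;
    precipitation-like layers are scaled by ``precip_scale`` and clamped
    at zero. Geometry is unchanged.
    """
    rng = np.random.default_rng(rng)
    K = len(stack.variables)
    n_temp = (K + 1) // 2
    geom = stack.geometry
    layers: dict[str, Grid] = {}
    for k, (name, grid) in enumerate(stack.layers.items()):
        if k < n_temp:
            if field_sd > 0:
                f = field_sd * _smooth_unit_field(
                    (geom.nrows, geom.ncols), range_len, rng
                )
            else:
                f = 0.0
            vals = grid.values + warming_delta + f
        else:
            vals = np.maximum(0.0, grid.values * precip_scale)
        layers[name] = grid.copy(values=vals)
    return RasterStack(layers)


def gen_pair(
    stack: RasterStack,
    offset_delta: float,
    seed: int | None = None,
    variables: list[str] | None = None,
    weight: float = 3.0,
    width: float = 1.0,
) -> tuple[SyntheticTruth, SyntheticTruth]:
    """Host and parasite truths whose niche optima differ by ``offset_delta``
    (in standardized layer units); overlap decreases as the offset grows."""
    if variables is None:
        variables = stack.variables[: min(2, len(stack.variables))]
    host_resp = [
        {"variable": v, "kind": "quadratic", "weight": weight,
         "optimum": 0.0, "width": width}
        for v in variables
    ]
    para_resp = [
        {"variable": v, "kind": "quadratic", "weight": weight,
         "optimum": offset_delta, "width": width}
        for v in variables
    ]
    host = gen_species(stack, host_resp, species="host", seed=seed)
    parasite = gen_species(stack, para_resp, species="parasite", seed=seed)
    return parasite, host


def truth_schoener_d(a: SyntheticTruth, b: SyntheticTruth) -> float:
    """Schoener's D between two truth suitability surfaces."""
    pa = a.suitability.values
    pb = b.suitability.values
    valid = np.isfinite(pa) & np.isfinite(pb)
    pa, pb = pa[valid], pb[valid]
    pa, pb = pa / pa.sum(), pb / pb.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


# ---------------------------------------------------------------------------
# Study emission (files the pipeline consumes)

def write_study(
    outdir: str | Path,
    stack: RasterStack,
    scenarios: dict[str, RasterStack],
    occurrences: dict[str, OccurrenceSet],
    mask: Grid | None = None,
    precision: int = 6,
) -> dict:
    """Write current + scenario grids, occurrence CSV, mask and a manifest."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"scenarios": {}, "occurrences": "occurrences.csv"}

    cur_dir = outdir / "current"
    write_stack(stack, cur_dir, precision)
    manifest["scenarios"]["current"] = {
        v: str(Path("current") / f"{v}.asc") for v in stack.variables
    }
    for name, sc in scenarios.items():
        d = outdir / name
        write_stack(sc, d, precision)
        manifest["scenarios"][name] = {
            v: str(Path(name) / f"{v}.asc") for v in sc.variables
        }
    if mask is None:
        geom = stack.geometry
        mask = geom.copy(values=np.ones((geom.nrows, geom.ncols)))
    write_ascii_grid(mask, outdir / "mask.asc", precision)
    manifest["mask"] = "mask.asc"

    import pandas as pd

    frames = [occ.to_frame() for occ in occurrences.values()]
    pd.concat(frames, ignore_index=True).to_csv(outdir / "occurrences.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
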