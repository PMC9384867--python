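"""Occurrence ingestion, spatial rarefaction and value extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import Grid, RasterStack

__all__ = [
    "OccurrenceSet",
    "SampleTable",
    "read_occurrences_csv",
    "read_all_occurrences",
    "spatial_rarefy",
    "sample_background",
    "extract_values",
]

log = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Cleaned presence coordinates for one species (WGS84 decimal degrees)."""

    species: str
    records: np.ndarray  # (n, 2) columns lon, lat
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 2)
        lon, lat = self.records[:, 0], self.records[:, 1]
        if self.records.size and (
            np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90)
        ):
            raise ValueError("coordinates outside WGS84 bounds")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "longitude": self.records[:, 0],
                "latitude": self.records[:, 1],
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass
class SampleTable:
    """Rows of climate values at presence (label 1) and background (label 0) cells."""

    variables: list[str]
    values: np.ndarray          # (n, K)
    label: np.ndarray           # (n,) int, 1 = presence
    cell: np.ndarray            # (n,) flat cell index row*ncols + col

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.label = np.asarray(self.label, dtype=int)
        self.cell = np.asarray(self.cell, dtype=int)
        n = self.values.shape[0]
        if not (len(self.label) == len(self.cell) == n):
            raise ValueError("SampleTable columns must have equal length")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("SampleTable rows may not sit on nodata cells")

    @property
    def presence(self) -> np.ndarray:
        return self.values[self.label == 1]

    @property
    def background(self) -> np.ndarray:
        return self.values[self.label == 0]

    @property
    def n_presence(self) -> int:
        return int(np.sum(self.label == 1))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variables)
        df.insert(0, "cell", self.cell)
        df["label"] = self.label
        return df


def concat_samples(parts: Sequence[SampleTable]) -> SampleTable:
    ref = parts[0]
    for p in parts[1:]:
        if p.variables != ref.variables:
            raise ValueError("cannot concatenate samples over differing variables")
    return SampleTable(
        variables=list(ref.variables),
        values=np.vstack([p.values for p in parts]),
        label=np.concatenate([p.label for p in parts]),
        cell=np.concatenate([p.cell for p in parts]),
    )


# ---------------------------------------------------------------------------
# CSV ingestion

def read_all_occurrences(
    path: str | Path,
    species_col: str = "species",
    lon_col: str = "longitude",
    lat_col: str = "latitude",
) -> dict[str, OccurrenceSet]:
    """Read a multi-species occurrence CSV into per-species OccurrenceSets.

    Exact duplicate coordinate pairs (within species) are removed and
    out-of-range rows rejected; counts of both are logged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {species_col, lon_col, lat_col} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    try:
        lon = pd.to_numeric(df[lon_col])
        lat = pd.to_numeric(df[lat_col])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable coordinate value: {exc}") from exc
    df = df.assign(**{lon_col: lon, lat_col: lat})

    in_range = (lon.abs() <= 180) & (lat.abs() <= 90) & lon.notna() & lat.notna()
    n_rejected = int((~in_range).sum())
    if n_rejected:
        log.warning("%s: rejected %d out-of-range rows", path, n_rejected)
    df = df[in_range]

    out: dict[str, OccurrenceSet] = {}
    for sp, group in df.groupby(species_col, sort=False):
        deduped = group.drop_duplicates(subset=[lon_col, lat_col], keep="first")
        n_dup = len(group) - len(deduped)
        if n_dup:
            log.info("%s / %s: removed %d duplicate records", path, sp, n_dup)
        out[str(sp)] = OccurrenceSet(
            species=str(sp),
            records=deduped[[lon_col, lat_col]].to_numpy(float),
            provenance=[str(path)],
        )
    return out


def read_occurrences_csv(
    path: str | Path,
    species: str | None = None,
    species_col: str = "species",
    lon_col: str = "longitude",
    lat_col: str = "latitude",
) -> OccurrenceSet:
    """Read one species' cleaned occurrences from a CSV file.

    If the file holds several species, ``species`` selects which one.
    """
    sets = read_all_occurrences(path, species_col, lon_col, lat_col)
    if species is None:
        if len(sets) != 1:
            raise ValueError(
                f"{path} holds {len(sets)} species; pass species= to choose one"
            )
        return next(iter(sets.values()))
    if species not in sets:
        raise ValueError(f"{path}: species {species!r} not found")
    return sets[species]


# ---------------------------------------------------------------------------
# Spatial rarefaction

def spatial_rarefy(occ: OccurrenceSet, geometry: Grid) -> OccurrenceSet:
    """Thin occurrences to at most one record per grid cell.

    The record kept in each occupied cell is the first one in input order.
    Points outside the grid extent are dropped (and counted in the log).
    """
    kept: list[int] = []
    seen: set[tuple[int, int]] = set()
    n_outside = 0
    for idx, (lon, lat) in enumerate(occ.records):
        try:
            cell = geometry.cell_of(lon, lat)
        except ValueError:
            n_outside += 1
            continue
        if cell not in seen:
            seen.add(cell)
            kept.append(idx)
    if n_outside:
        log.warning("%s: dropped %d records outside grid extent", occ.species, n_outside)
    if not kept:
        raise ValueError(
            f"{occ.species}: no records remain after rarefaction; "
            "use a coarser grid or supply more records"
        )
    return OccurrenceSet(
        species=occ.species,
        records=occ.records[kept],
        provenance=occ.provenance + [f"rarefied to {geometry.cellsize} deg cells"],
    )


# ---------------------------------------------------------------------------
# Sampling and extraction

def sample_background(
    stack: RasterStack,
    mask: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> SampleTable:
    """Draw n distinct background cells uniformly from mask-true cells.

    If n exceeds the number of valid cells, all valid cells are used (with a
    warning). Reproducible given a seeded generator.
    """
    rng = np.random.default_rng(rng)
    flat_valid = np.flatnonzero(mask.ravel())
    if flat_valid.size == 0:
        raise ValueError("background mask has no valid cells")
    if n >= flat_valid.size:
        if n > flat_valid.size:
            log.warning(
                "requested %d background points but only %d valid cells; using all",
                n, flat_valid.size,
            )
        chosen = flat_valid
    else:
        chosen = rng.choice(flat_valid, size=n, replace=False)
        chosen = np.sort(chosen)
    arr = stack.to_array()  # (K, nrows, ncols)
    flat = arr.reshape(len(stack.variables), -1)
    vals = flat[:, chosen].T
    return SampleTable(
        variables=stack.variables,
        values=vals,
        label=np.zeros(len(chosen), dtype=int),
        cell=chosen,
    )


def extract_values(
    stack: RasterStack,
    points: np.ndarray | OccurrenceSet,
    label: int = 1,
) -> SampleTable:
    """Extract every layer's value at each point's containing cell.

    Points on nodata cells are dropped and reported; points outside the
    extent raise.
    """
    if isinstance(points, OccurrenceSet):
        pts = points.records
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    geom = stack.geometry
    arr = stack.to_array()
    cells = np.empty(len(pts), dtype=int)
    for k, (lon, lat) in enumerate(pts):
        i, j = geom.cell_of(lon, lat)
        cells[k] = i * geom.ncols + j
    flat = arr.reshape(len(stack.variables), -1)
    vals = flat[:, cells].T
    ok = np.all(np.isfinite(vals), axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("dropped %d points on nodata cells", n_dropped)
    return SampleTable(
        variables=stack.variables,
        values=vals[ok],
        label=np.full(int(ok.sum()), label, dtype=int),
        cell=cells[ok],
    )
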