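"""Gridded climate layers: ESRI ASCII I/O, alignment, masking, ensembles.

Grids are stored row-major with row 0 = northernmost row. Nodata cells are
held as NaN in memory; the ``nodata`` attribute records the sentinel used
on disk. The canonical georeference is the lower-left *corner* (xllcorner /
yllcorner); center-form headers are converted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Grid",
    "RasterStack",
    "ScenarioSet",
    "GridFormatError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "ensemble_mean",
    "intersect_mask",
]


class GridFormatError(ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed."""


class AlignmentError(ValueError):
    """Raised when grids that must share geometry do not."""


@dataclass
class Grid:
    """A georeferenced cell lattice.

    Cell (i, j) covers the half-open box
    [xll + j*cs, xll + (j+1)*cs) x [yll + (nrows-1-i)*cs, yll + (nrows-i)*cs),
    so row 0 is the northernmost row and a point on a shared edge belongs to
    the cell north-east of it never — edges are owned by the cell whose
    lower-left corner they touch.
    """

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")
        if self.values is None:
            self.values = np.full((self.nrows, self.ncols), np.nan)
        self.values = np.asarray(self.values, dtype=float).reshape(
            self.nrows, self.ncols
        )

    # -- geometry ---------------------------------------------------------

    @property
    def geometry(self) -> tuple[int, int, float, float, float]:
        return (self.nrows, self.ncols, self.xll, self.yll, self.cellsize)

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        if (self.nrows, self.ncols) != (other.nrows, other.ncols):
            return False
        return (
            abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a point to its containing cell under the half-open rule.

        Raises ValueError for points outside the grid extent.
        """
        cs = self.cellsize
        j = math.floor((lon - self.xll) / cs)
        row_from_south = math.floor((lat - self.yll) / cs)
        i = self.nrows - 1 - row_from_south
        if not (0 <= i < self.nrows and 0 <= j < self.ncols):
            raise ValueError(
                f"point ({lon}, {lat}) outside grid extent "
                f"[{self.xll}, {self.xll + self.ncols * cs}) x "
                f"[{self.yll}, {self.yll + self.nrows * cs})"
            )
        return i, j

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        lon = self.xll + (j + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - 1 - i + 0.5) * self.cellsize
        return lon, lat

    # -- nodata -----------------------------------------------------------

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        v = self.values.copy() if values is None else np.asarray(values, float)
        return replace(self, values=v)


@dataclass
class RasterStack:
    """Ordered mapping of variable name -> Grid, all on one geometry."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("RasterStack needs at least one layer")
        grids = list(self.layers.values())
        ref = grids[0]
        for name, g in self.layers.items():
            if not g.same_geometry(ref):
                raise AlignmentError(f"layer {name!r} geometry differs from first layer")

    @property
    def variables(self) -> list[str]:
        return list(self.layers.keys())

    @property
    def geometry(self) -> Grid:
        """A reference grid (first layer) carrying the shared geometry."""
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack({n: self.layers[n] for n in names})

    def to_array(self) -> np.ndarray:
        """(n_layers, nrows, ncols) array with NaN at nodata."""
        return np.stack([g.values for g in self.layers.values()])


@dataclass
class ScenarioSet:
    """A named climate scenario: one or more GCM members and their ensemble."""

    name: str
    members: list[RasterStack]
    ensemble: RasterStack = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ensemble is None:
            self.ensemble = ensemble_mean(self.members)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid (corner or center dialect).

    Center-form headers are converted to the corner convention
    (xll = xllcenter - cellsize/2). NODATA cells come back as NaN.
    """
    path = Path(path)
    header: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key in _HEADER_KEYS:
            if len(parts) != 2:
                raise GridFormatError(
                    f"{path}: malformed header line {lineno + 1}: {line.strip()!r}"
                )
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: non-numeric header value on line {lineno + 1}: "
                    f"{line.strip()!r}"
                ) from exc
            body_start = lineno + 1
        else:
            break

    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise GridFormatError(f"{path}: missing header key {required!r}")
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - header["cellsize"] / 2.0
    else:
        raise GridFormatError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - header["cellsize"] / 2.0
    else:
        raise GridFormatError(f"{path}: missing yllcorner/yllcenter")

    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)

    tokens = " ".join(lines[body_start:]).split()
    try:
        flat = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: non-numeric data value: {exc}") from exc
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    values = np.where(np.isclose(values, nodata), np.nan, values)
    return Grid(nrows=nrows, ncols=ncols, xll=xll, yll=yll,
                cellsize=header["cellsize"], nodata=nodata, values=values)


def write_ascii_grid(grid: Grid, path: str | Path, precision: int = 6) -> Path:
    """Write a Grid as an ESRI ASCII file (corner dialect, lowercase keys)."""
    path = Path(path)
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    fmt = f"%.{precision}g"
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"nodata_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(fmt % v for v in row))
            fh.write("\n")
    return path


def read_stack(paths: Mapping[str, str | Path]) -> RasterStack:
    """Read a set of variable -> file mappings into a RasterStack."""
    return RasterStack({name: read_ascii_grid(p) for name, p in paths.items()})


def write_stack(stack: RasterStack, outdir: str | Path, precision: int = 6) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, grid in stack.layers.items():
        out[name] = write_ascii_grid(grid, outdir / f"{name}.asc", precision)
    return out


# ---------------------------------------------------------------------------
# Ensembles and masks

def ensemble_mean(
    members: Sequence[RasterStack], weights: Sequence[float] | None = None
) -> RasterStack:
    """Weighted per-cell, per-variable mean of GCM members.

    Weights default to equal and must sum to 1. A nodata cell in any member
    propagates to nodata in the output.
    """
    if not members:
        raise ValueError("ensemble_mean needs at least one member")
    ref = members[0]
    names = ref.variables
    for m in members[1:]:
        if m.variables != names:
            raise AlignmentError("ensemble members have differing variable names")
        if not m.geometry.same_geometry(ref.geometry):
            raise AlignmentError("ensemble members have differing geometry")
    if weights is None:
        weights = [1.0 / len(members)] * len(members)
    if len(weights) != len(members):
        raise ValueError("one weight per member required")
    if abs(sum(weights) - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")

    layers: dict[str, Grid] = {}
    for name in names:
        acc = np.zeros_like(ref[name].values)
        for w, m in zip(weights, members):
            acc = acc + w * m[name].values  # NaN propagates
        layers[name] = ref[name].copy(values=acc)
    return RasterStack(layers)


def intersect_mask(*items: Grid | RasterStack) -> np.ndarray:
    """Boolean mask, True exactly where every input grid/layer holds data."""
    grids: list[Grid] = []
    for item in items:
        if isinstance(item, RasterStack):
            grids.extend(item.layers.values())
        else:
            grids.append(item)
    if not grids:
        raise ValueError("intersect_mask needs at least one grid")
    ref = grids[0]
    mask = np.ones((ref.nrows, ref.ncols), dtype=bool)
    for g in grids:
        if not g.same_geometry(ref):
            raise AlignmentError("cannot intersect masks over differing geometries")
        mask &= g.valid
    return mask


def mask_grid(mask: np.ndarray, template: Grid) -> Grid:
    """Wrap a boolean mask as a 0/1 Grid on the template's geometry."""
    return template.copy(values=mask.astype(float))
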