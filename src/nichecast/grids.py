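"""Raster/point data model and small geographic statistics.

The data model is deliberately planar and minimal: a :class:`GridSpec`
describes a regular north-up grid in arbitrary planar coordinates, a
:class:`Layer` holds one value per cell with a NaN-based nodata mask, and a
:class:`PredictorStack` is an ordered, named collection of co-registered
layers (one environmental scenario).  Cell ``(r, c)`` covers the half-open
square ``[x0 + c*s, x0 + (c+1)*s) x (y_top - (r+1)*s, y_top - r*s]`` with
row 0 at the top, so a point on a shared vertical edge belongs to the cell
whose left edge it is, and a point on a shared horizontal edge belongs to
the lower cell (whose top edge is closed).

Geographic CRS handling (datums, reprojection) is out of scope: callers
must supply co-registered stacks.  A nearest-neighbour resampling utility
is provided for convenience only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nichecast")

__all__ = [
    "GridSpec",
    "Layer",
    "PredictorStack",
    "OccurrenceSet",
    "SampleMatrix",
    "extract_values",
    "correlation_screen",
    "morans_i",
    "region_occurrence_stats",
    "region_percentages",
    "latitudinal_profile",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "resample_nearest",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular, north-up planar grid."""

    x_origin: float
    y_top: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def y_bottom(self) -> float:
        return self.y_top - self.n_rows * self.cell_size

    @property
    def x_right(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col, in_bounds) under the half-open convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        r = np.floor((self.y_top - y) / self.cell_size).astype(int)
        # top edge of the grid is closed: y == y_top belongs to row 0
        r = np.where(y == self.y_top, 0, r)
        ok = (c >= 0) & (c < self.n_cols) & (r >= 0) & (r < self.n_rows)
        return r, c, ok

    def cell_center(self, r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x_origin + (np.asarray(c) + 0.5) * self.cell_size
        y = self.y_top - (np.asarray(r) + 0.5) * self.cell_size
        return x, y

    def row_centers_y(self) -> np.ndarray:
        return self.y_top - (np.arange(self.n_rows) + 0.5) * self.cell_size


@dataclass
class Layer:
    """One raster band: a float array with NaN marking nodata."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def copy(self) -> "Layer":
        return Layer(self.grid, self.values.copy())


class PredictorStack:
    """Named, co-registered raster layers sharing one :class:`GridSpec`."""

    def __init__(self, layers: Mapping[str, Layer]):
        if not layers:
            raise ValueError("stack must contain at least one layer")
        grids = {id(l.grid): l.grid for l in layers.values()}
        first = next(iter(layers.values())).grid
        for l in layers.values():
            if l.grid != first:
                raise ValueError("all layers in a stack must share one GridSpec")
        self._layers: dict[str, Layer] = dict(layers)
        self.grid = first

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __getitem__(self, name: str) -> Layer:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    def copy(self) -> "PredictorStack":
        return PredictorStack({n: l.copy() for n, l in self._layers.items()})

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.grid.shape, dtype=bool)
        for l in self._layers.values():
            m &= l.valid_mask
        return m

    def to_matrix(self, mask: np.ndarray | None = None) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        """Flatten valid cells to a (cells x predictors) frame plus row/col indices."""
        if mask is None:
            mask = self.valid_mask()
        rr, cc = np.nonzero(mask)
        data = {n: l.values[rr, cc] for n, l in self._layers.items()}
        return pd.DataFrame(data), rr, cc


@dataclass
class OccurrenceSet:
    """Presence points for one species, optionally tagged by region."""

    species_id: str
    x: np.ndarray
    y: np.ndarray
    region: np.ndarray | None = None  # per-point label or None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
            if self.region.shape != self.x.shape:
                raise ValueError("region labels must match point count")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class SampleMatrix:
    """Extracted predictor values per point, with optional 0/1 response.

    ``frame`` columns follow ``predictors`` order; ``response`` (if present)
    is a 0/1 array aligned with the rows.  Rows from out-of-bounds or nodata
    points are dropped at construction and tallied in ``n_dropped``.
    """

    frame: pd.DataFrame
    predictors: list[str]
    response: np.ndarray | None = None
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.frame)

    def values(self) -> np.ndarray:
        return self.frame[self.predictors].to_numpy(dtype=float)

    def with_response(self, response: Iterable[int]) -> "SampleMatrix":
        r = np.asarray(list(response), dtype=int)
        if r.size != len(self.frame):
            raise ValueError("response length must match rows")
        return SampleMatrix(self.frame, self.predictors, r, self.n_dropped)


def extract_values(stack: PredictorStack, x, y) -> SampleMatrix:
    """Extract the containing cell's value for each point, per layer.

    Out-of-bounds points and points in nodata cells are excluded with a
    logged warning; the dropped count is recorded on the result.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    names = stack.names
    if x.size == 0:
        return SampleMatrix(pd.DataFrame(columns=names), names)
    r, c, ok = stack.grid.cell_of(x, y)
    n_oob = int((~ok).sum())
    if n_oob:
        logger.warning("extract_values: %d point(s) out of bounds, excluded", n_oob)
    r, c = r[ok], c[ok]
    data = {n: stack[n].values[r, c] for n in names}
    frame = pd.DataFrame(data)
    nodata_rows = ~np.isfinite(frame.to_numpy()).all(axis=1)
    n_nodata = int(nodata_rows.sum())
    if n_nodata:
        logger.warning("extract_values: %d point(s) in nodata cells, excluded", n_nodata)
        frame = frame.loc[~nodata_rows].reset_index(drop=True)
    return SampleMatrix(frame, names, n_dropped=n_oob + n_nodata)


def correlation_screen(
    matrix: SampleMatrix | pd.DataFrame, threshold: float = 0.85
) -> tuple[list[str], pd.DataFrame]:
    """Greedy Pearson screen: drop a predictor iff |r| > threshold with one already kept.

    The pass walks predictors in the given column order ("first listed wins").
    Returns the retained names and the full pairwise correlation matrix.
    Zero-variance columns have undefined correlations; they are retained and
    flagged with a warning.
    """
    frame = matrix.frame if isinstance(matrix, SampleMatrix) else matrix
    if len(frame) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    if frame.shape[1] < 1:
        raise ValueError("correlation screen needs at least 1 column")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = frame.corr(method="pearson")
    degenerate = [c for c in frame.columns if frame[c].nunique() <= 1]
    for c in degenerate:
        logger.warning("correlation_screen: column %r has zero variance; retained", c)
    retained: list[str] = []
    for name in frame.columns:
        if name in degenerate:
            retained.append(name)
            continue
        r_with_kept = [
            abs(corr.loc[name, k]) for k in retained if k not in degenerate
        ]
        if any(r > threshold for r in r_with_kept if np.isfinite(r)):
            continue
        retained.append(name)
    return retained, corr


def _contiguity_pairs(shape: tuple[int, int], contiguity: str) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) of neighbouring cells, both directions, flat indexing."""
    n_rows, n_cols = shape
    idx = np.arange(n_rows * n_cols).reshape(shape)
    if contiguity == "rook":
        offsets = [(0, 1), (1, 0)]
    elif contiguity == "queen":
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    else:
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    src, dst = [], []
    for dr, dc in offsets:
        ra = slice(max(0, -dr), n_rows - max(0, dr))
        rb = slice(max(0, dr), n_rows - max(0, -dr))
        ca = slice(max(0, -dc), n_cols - max(0, dc))
        cb = slice(max(0, dc), n_cols - max(0, -dc))
        a = idx[ra, ca]
        b = idx[rb, cb]
        src.append(a.ravel())
        dst.append(b.ravel())
    i = np.concatenate(src + dst)
    j = np.concatenate(dst + src)
    return i, j


def morans_i(
    layer: Layer | np.ndarray,
    contiguity: str = "rook",
    inference: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Global Moran's I with binary, row-unstandardized contiguity weights.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    where S0 is the total weight.  Nodata cells are removed from the lattice
    (their incident weights vanish).  Two-sided p-value either by random
    permutation of values over cells or by the normal approximation under
    randomization.
    """
    values = layer.values if isinstance(layer, Layer) else np.asarray(layer, dtype=float)
    shape = values.shape
    flat = values.ravel()
    valid = np.isfinite(flat)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("Moran's I needs at least 2 valid cells")
    x = flat[valid]
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for a constant field (zero variance)")
    i_all, j_all = _contiguity_pairs(shape, contiguity)
    keep = valid[i_all] & valid[j_all]
    # reindex into the compacted valid-cell vector
    pos = -np.ones(flat.size, dtype=int)
    pos[valid] = np.arange(n)
    wi, wj = pos[i_all[keep]], pos[j_all[keep]]
    s0 = float(wi.size)  # binary weights

    def stat(v: np.ndarray) -> float:
        z = v - v.mean()
        return (n / s0) * float(np.dot(z[wi], z[wj])) / float(np.dot(z, z))

    i_obs = stat(x)
    e_i = -1.0 / (n - 1)
    if inference == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = stat(rng.permutation(x))
        # two-sided: fraction of permutations at least as extreme around E[I]
        p = (1 + np.sum(np.abs(null - e_i) >= abs(i_obs - e_i))) / (1 + n_perm)
        sd = null.std(ddof=1)
        z = (i_obs - null.mean()) / sd if sd > 0 else np.nan
    elif inference == "normal":
        # randomization variance (binary symmetric weights): standard moments
        s1 = 2.0 * s0  # binary symmetric: S1 = (1/2) sum (w_ij + w_ji)^2 = 2*S0
        row = np.bincount(wi, minlength=n).astype(float)
        s2 = float(np.sum((2 * row) ** 2))  # S2 = sum_i (w_i. + w_.i)^2
        zc = x - x.mean()
        b2 = n * np.sum(zc**4) / (np.sum(zc**2) ** 2)
        a = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        b = b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        var = (a - b) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        from scipy.stats import norm

        z = (i_obs - e_i) / math.sqrt(var)
        p = 2 * norm.sf(abs(z))
    else:
        raise ValueError("inference must be 'permutation' or 'normal'")
    return {"I": i_obs, "expected": e_i, "z": float(z), "p": float(p)}


def region_occurrence_stats(occ: OccurrenceSet, region_layer: Layer) -> pd.DataFrame:
    """Per-region occurrence counts and percentages (one decimal).

    ``region_layer`` holds integer (or category-coded) region labels per cell;
    points in nodata/unlabelled cells are tallied under ``"unassigned"`` with
    a warning.  Percentages are 100*count/total rounded to one decimal.
    """
    r, c, ok = region_layer.grid.cell_of(occ.x, occ.y)
    labels: list[object] = []
    n_oob = int((~ok).sum())
    vals = np.full(occ.x.size, np.nan)
    vals[ok] = region_layer.values[r[ok], c[ok]]
    for i in range(occ.x.size):
        if not ok[i] or not np.isfinite(vals[i]):
            labels.append("unassigned")
        else:
            labels.append(vals[i])
    n_un = sum(1 for l in labels if l == "unassigned")
    if n_un:
        logger.warning("region_occurrence_stats: %d point(s) unassigned", n_un)
    ser = pd.Series(labels)
    counts = ser.value_counts()
    counts = counts.loc[sorted(counts.index, key=str)]
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts.astype(int)})
    out["percent"] = (100.0 * out["count"] / total).round(1)
    out.index.name = "region"
    return out


def region_percentages(counts: Mapping[str, int]) -> pd.DataFrame:
    """Percentages (one decimal) from raw per-region counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return pd.DataFrame(
        {
            "count": list(counts.values()),
            "percent": [round(100.0 * v / total, 1) for v in counts.values()],
        },
        index=list(counts.keys()),
    )


def latitudinal_profile(layer: Layer, band_width: float) -> pd.DataFrame:
    """Mean layer value in horizontal latitude bands tiling the y-extent.

    Bands start at the bottom of the grid; the band count is
    ceil(y_extent / band_width).  Bands with no valid cell get NaN.
    """
    if band_width <= 0:
        raise ValueError("band_width must be > 0")
    g = layer.grid
    extent = g.n_rows * g.cell_size
    n_bands = max(1, math.ceil(extent / band_width))
    y_centers = g.row_centers_y()
    band_idx = np.floor((y_centers - g.y_bottom) / band_width).astype(int)
    band_idx = np.clip(band_idx, 0, n_bands - 1)
    centers = g.y_bottom + (np.arange(n_bands) + 0.5) * band_width
    means = np.full(n_bands, np.nan)
    counts = np.zeros(n_bands, dtype=int)
    for b in range(n_bands):
        rows = np.nonzero(band_idx == b)[0]
        if rows.size == 0:
            continue
        vals = layer.values[rows, :]
        finite = np.isfinite(vals)
        counts[b] = int(finite.sum())
        if counts[b]:
            means[b] = float(vals[finite].mean())
    return pd.DataFrame({"band_center_y": centers, "mean": means, "n_cells": counts})


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and occurrence CSV


def write_ascii_grid(layer: Layer, path, nodata: float = -9999.0) -> None:
    g = layer.grid
    vals = np.where(np.isfinite(layer.values), layer.values, nodata)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.x_origin!r}\n"
        f"yllcorner {g.y_bottom!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Layer:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"grid body shape {vals.shape} != header ({n_rows}, {n_cols})")
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    grid = GridSpec(
        x_origin=header["xllcorner"],
        y_top=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return Layer(grid, vals)


def write_occurrences_csv(occ: OccurrenceSet, path) -> None:
    frame = pd.DataFrame({"species": occ.species_id, "x": occ.x, "y": occ.y})
    if occ.region is not None:
        frame["region"] = occ.region
    frame.to_csv(path, index=False)


def read_occurrences_csv(path, species_id: str | None = None) -> OccurrenceSet:
    frame = pd.read_csv(path)
    if species_id is not None:
        frame = frame[frame["species"] == species_id]
    elif frame["species"].nunique() > 1:
        raise ValueError("CSV holds multiple species; pass species_id")
    region = frame["region"].to_numpy() if "region" in frame.columns else None
    sid = species_id if species_id is not None else str(frame["species"].iloc[0])
    return OccurrenceSet(sid, frame["x"].to_numpy(), frame["y"].to_numpy(), region)


def resample_nearest(layer: Layer, target: GridSpec) -> Layer:
    """Nearest-neighbour resample onto another grid (convenience only)."""
    xc, yc = np.meshgrid(
        target.x_origin + (np.arange(target.n_cols) + 0.5) * target.cell_size,
        target.row_centers_y(),
    )
    r, c, ok = layer.grid.cell_of(xc.ravel(), yc.ravel())
    out = np.full(xc.size, np.nan)
    out[ok] = layer.values[r[ok], c[ok]]
    return Layer(target, out.reshape(target.shape))
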