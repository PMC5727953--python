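"""Extrapolation detection (MESS), the MEDI transform, and multi-GCM consensus.

Hindcasting a suitability model onto a paleoclimate scenario can require
predicting in environments absent from the training data.  The multivariate
environmental similarity surface (MESS) quantifies this per cell: for each
variable, a percentile-based similarity to a reference sample is computed,
and the cell's MES is the minimum across variables — negative where at
least one variable falls outside the reference range (non-analog climate).

Because MES can be negative, it cannot weight a consensus average directly.
The dissimilarity transform MEDI = 100 - MES is strictly positive wherever
MES < 100, so the inverse-MEDI weighted average

    Proj_WA = sum_i (1/MEDI_i) * Proj_i / sum_i (1/MEDI_i)

down-weights the projections of climate models whose hindcasted climates
are most novel relative to the training conditions, while staying inside
the per-cell range of the input projections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import Layer, PredictorStack, SampleMatrix
from .sdm import ProjectionResult

logger = logging.getLogger("nichecast")

__all__ = [
    "MessResult",
    "MediLayer",
    "ConsensusProjection",
    "compute_mess",
    "mes_to_medi",
    "extrapolated_area_fraction",
    "consensus",
    "summarize_medi_at_points",
]

NEG_SENTINEL = -1e9  # similarity when a degenerate (min==max) variable is exceeded


def _mess_similarity(ref: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Per-variable similarity on the percent scale.

    With f = 100 * fraction of reference values strictly below v:
      f = 0          -> S = 100 * (v - min) / (max - min)
      0 < f <= 50    -> S = 2 f
      50 <= f < 100  -> S = 2 (100 - f)
      f = 100        -> S = 100 * (max - v) / (max - min)
    Ties count as "not below" (strict inequality).
    """
    ref = np.sort(np.asarray(ref, dtype=float))
    v = np.asarray(v, dtype=float)
    n = ref.size
    lo, hi = ref[0], ref[-1]
    below = np.searchsorted(ref, v, side="left")
    f = 100.0 * below / n
    span = hi - lo
    s = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
    if span > 0:
        s = np.where(f == 0.0, 100.0 * (v - lo) / span, s)
        s = np.where(f == 100.0, 100.0 * (hi - v) / span, s)
    else:
        out_of_range = (v != lo) & ((f == 0.0) | (f == 100.0))
        if np.any(out_of_range):
            logger.warning(
                "MESS: degenerate reference (min == max) exceeded; using large negative sentinel"
            )
        s = np.where(out_of_range, NEG_SENTINEL, s)
    return s


@dataclass
class MessResult:
    """Per-cell MES (min over variables) plus optional per-variable layers."""

    mes: Layer
    per_variable: dict[str, Layer] = field(default_factory=dict)
    reference_summary: pd.DataFrame | None = None


def compute_mess(
    reference: SampleMatrix | pd.DataFrame,
    stack: PredictorStack,
    keep_per_variable: bool = True,
) -> MessResult:
    """MESS of a scenario stack relative to a reference sample.

    The reference is typically the training sample (presences plus
    pseudo-absences) under current conditions; the stack is the scenario to
    be screened for non-analog climate.
    """
    frame = reference.frame if isinstance(reference, SampleMatrix) else pd.DataFrame(reference)
    variables = [c for c in frame.columns if c in stack]
    missing = [c for c in frame.columns if c not in stack]
    if missing:
        raise ValueError(f"stack lacks reference variable(s): {missing}")
    if len(frame) < 2:
        raise ValueError("reference needs at least 2 rows")
    mask = stack.valid_mask()
    mes_vals = np.full(stack.grid.shape, np.inf)
    per_var: dict[str, Layer] = {}
    summary = []
    for var in variables:
        ref = frame[var].to_numpy(dtype=float)
        s = np.full(stack.grid.shape, np.nan)
        s[mask] = _mess_similarity(ref, stack[var].values[mask])
        mes_vals = np.minimum(mes_vals, np.where(mask, s, np.inf))
        if keep_per_variable:
            per_var[var] = Layer(stack.grid, s)
        summary.append({"variable": var, "min": ref.min(), "max": ref.max(), "n": ref.size})
    mes_vals = np.where(mask, mes_vals, np.nan)
    return MessResult(
        Layer(stack.grid, mes_vals),
        per_var,
        pd.DataFrame(summary).set_index("variable"),
    )


@dataclass
class MediLayer:
    """Dissimilarity layer MEDI = 100 - MES (NaN preserved)."""

    layer: Layer

    def mean(self) -> float:
        return float(np.nanmean(self.layer.values))


def mes_to_medi(mess: MessResult | Layer) -> MediLayer:
    layer = mess.mes if isinstance(mess, MessResult) else mess
    return MediLayer(Layer(layer.grid, 100.0 - layer.values))


def extrapolated_area_fraction(mess: MessResult | Layer, threshold: float = -20.0) -> float:
    """Percent of valid cells with MES below the threshold, to one decimal."""
    layer = mess.mes if isinstance(mess, MessResult) else mess
    vals = layer.valid_values()
    if vals.size == 0:
        raise ValueError("no valid cells")
    return round(100.0 * float(np.sum(vals < threshold)) / vals.size, 1)


def summarize_medi_at_points(
    medi: MediLayer, reference_xy: tuple[np.ndarray, np.ndarray], statistic: str = "mean"
) -> float:
    """Scalar MEDI weight for one GCM: environmental novelty of its scenario
    evaluated at the reference (presence + background) points."""
    x, y = reference_xy
    r, c, ok = medi.layer.grid.cell_of(x, y)
    vals = medi.layer.values[r[ok], c[ok]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no reference points fall on valid MEDI cells")
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "median":
        return float(np.median(vals))
    raise ValueError("statistic must be 'mean' or 'median'")


@dataclass
class ConsensusProjection:
    combined: Layer
    method: str
    weights: dict[str, float | np.ndarray] = field(default_factory=dict)


def consensus(
    projections: Mapping[str, ProjectionResult | Layer],
    medis: Mapping[str, float | MediLayer] | None = None,
    method: str = "mean",
) -> ConsensusProjection:
    """Combine per-GCM projections by plain mean or inverse-MEDI weighting.

    For ``medi_weighted``, each GCM contributes a weight 1/MEDI, either a
    scalar (novelty summarized over the reference points, the default
    workflow) or a per-cell MEDI layer.  Weights must be positive: MEDI <= 0
    would mean MES > 100, impossible on the percent scale, so it is treated
    as an error.  The combined value always lies within the per-cell
    min/max of the inputs.
    """
    if len(projections) < 2:
        raise ValueError("consensus needs at least 2 projections")
    layers = {
        g: (p.suitability if isinstance(p, ProjectionResult) else p)
        for g, p in projections.items()
    }
    grids = {id(l.grid) for l in layers.values()}
    first = next(iter(layers.values()))
    for l in layers.values():
        if l.grid != first.grid:
            raise ValueError("projection grids do not match")
    arr = np.stack([l.values for l in layers.values()])
    if method == "mean":
        combined = arr.mean(axis=0)
        return ConsensusProjection(Layer(first.grid, combined), "mean")
    if method != "medi_weighted":
        raise ValueError(f"unknown consensus method {method!r}")
    if medis is None:
        raise ValueError("medi_weighted consensus needs a MEDI per GCM")
    w_list = []
    used: dict[str, float | np.ndarray] = {}
    for g in layers:
        if g not in medis:
            raise ValueError(f"no MEDI supplied for GCM {g!r}")
        m = medis[g]
        mv = m.layer.values if isinstance(m, MediLayer) else float(m)
        if np.any(np.asarray(mv) <= 0):
            raise ValueError(f"MEDI <= 0 for GCM {g!r}: inverse weight undefined")
        w = 1.0 / mv
        w_list.append(np.broadcast_to(np.asarray(w, dtype=float), first.grid.shape))
        used[g] = mv
    w_arr = np.stack(w_list)
    combined = (w_arr * arr).sum(axis=0) / w_arr.sum(axis=0)
    return ConsensusProjection(Layer(first.grid, combined), "medi_weighted", used)
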