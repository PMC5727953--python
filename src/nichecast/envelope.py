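"""Two-step pseudo-absence selection with environmental profiling.

Stage 1 profiles the presence environment with a rectilinear percentile
envelope (the classic "bioclim" model): per predictor, a cell scores by how
central its value is within the presence reference distribution, and the
cell score is the minimum across predictors.  Stage 2 discretizes the
continuous envelope surface into five natural-breaks classes and samples
pseudo-absences uniformly from the cells of the three lowest-suitability
classes, at a 1:1 ratio with the presences, so that the pseudo-absences
behave as plausible true absences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grids import GridSpec, Layer, PredictorStack, SampleMatrix

logger = logging.getLogger("nichecast")

__all__ = [
    "BioclimEnvelope",
    "ClassifiedSuitability",
    "PseudoAbsenceSet",
    "fit_envelope",
    "envelope_score",
    "jenks_breaks",
    "jenks_classify",
    "sample_pseudoabsences",
]


class BioclimEnvelope(BaseEstimator):
    """Rectilinear percentile-envelope presence model.

    For each fitted predictor the score of a value ``v`` is ``2*min(p, 1-p)``
    where ``p`` is the empirical fraction of reference values <= ``v`` with a
    midpoint convention for ties: ``p = (#less + 0.5*#equal) / n``.  Values
    outside the fitted [min, max] on any predictor score 0.  The cell score
    is the minimum across predictors, so the envelope is 1.0 only at the
    joint per-predictor medians.

    Fitting is deterministic: the model just stores the sorted presence
    reference values per predictor.
    """

    def fit(self, X: SampleMatrix | pd.DataFrame, y=None) -> "BioclimEnvelope":
        frame = X.frame if isinstance(X, SampleMatrix) else pd.DataFrame(X)
        if len(frame) < 5:
            raise ValueError("envelope needs at least 5 presence rows")
        arr = frame.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("presence matrix contains nodata/non-finite values")
        self.feature_names_in_ = list(frame.columns)
        self.reference_ = {c: np.sort(frame[c].to_numpy(dtype=float)) for c in frame.columns}
        for c, ref in self.reference_.items():
            if ref[0] == ref[-1]:
                logger.warning(
                    "envelope: predictor %r has zero variance; envelope collapses to a point", c
                )
        return self

    def score_values(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Envelope score for aligned per-predictor value arrays."""
        score = None
        for name in self.feature_names_in_:
            if name not in values:
                raise ValueError(f"missing predictor {name!r} at score time")
            v = np.asarray(values[name], dtype=float)
            ref = self.reference_[name]
            n = ref.size
            less = np.searchsorted(ref, v, side="left")
            leq = np.searchsorted(ref, v, side="right")
            p = (less + 0.5 * (leq - less)) / n
            s = 2.0 * np.minimum(p, 1.0 - p)
            s = np.where((v < ref[0]) | (v > ref[-1]), 0.0, s)
            score = s if score is None else np.minimum(score, s)
        return np.asarray(score)

    def score_samples(self, X: SampleMatrix | pd.DataFrame) -> np.ndarray:
        frame = X.frame if isinstance(X, SampleMatrix) else pd.DataFrame(X)
        return self.score_values({c: frame[c].to_numpy(dtype=float) for c in self.feature_names_in_})

    def score_stack(self, stack: PredictorStack) -> Layer:
        """Project the envelope over a stack; nodata propagates."""
        vals = {}
        for name in self.feature_names_in_:
            if name not in stack:
                raise ValueError(f"stack lacks fitted predictor {name!r}")
            vals[name] = stack[name].values
        s = self.score_values(vals)
        s = np.where(stack.valid_mask(), s, np.nan)
        return Layer(stack.grid, s)


def fit_envelope(presence_matrix: SampleMatrix | pd.DataFrame) -> BioclimEnvelope:
    return BioclimEnvelope().fit(presence_matrix)


def envelope_score(model: BioclimEnvelope, stack: PredictorStack) -> Layer:
    return model.score_stack(stack)


def jenks_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Exact Jenks natural breaks (Fisher's optimal 1-D partition).

    Dynamic programming over the sorted unique values with multiplicities,
    minimizing the total within-class sum of squared deviations.  Returns
    the k-1 interior break points, each the midpoint between the last value
    of a class and the first value of the next (ties at a break go to the
    lower class).
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    uniq, counts = np.unique(values, return_counts=True)
    m = uniq.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if m < k:
        raise ValueError(f"need at least k={k} distinct values, got {m}")
    if k == 1:
        return np.array([])
    # prefix sums for O(1) within-class SSD of any run [i, j]
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * uniq)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * uniq * uniq)])

    def ssd(i: int, j: int) -> float:
        # classes cover unique values i..j inclusive
        n = cw[j + 1] - cw[i]
        s = cwx[j + 1] - cwx[i]
        s2 = cwx2[j + 1] - cwx2[i]
        return s2 - s * s / n

    # dp[c][j] = min total SSD partitioning uniq[0..j] into c+1 classes
    inf = np.inf
    dp = np.full((k, m), inf)
    back = np.zeros((k, m), dtype=int)
    for j in range(m):
        dp[0, j] = ssd(0, j)
    for c in range(1, k):
        for j in range(c, m):
            best, arg = inf, c
            for i in range(c, j + 1):  # class c starts at uniq[i]
                cand = dp[c - 1, i - 1] + ssd(i, j)
                if cand < best:
                    best, arg = cand, i
            dp[c, j] = best
            back[c, j] = arg
    # recover class start indices
    starts = []
    j = m - 1
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        starts.append(i)
        j = i - 1
    starts = sorted(starts)
    return np.array([(uniq[i - 1] + uniq[i]) / 2.0 for i in starts])


@dataclass
class ClassifiedSuitability:
    """Integer class layer (1 = lowest suitability) plus its break points."""

    classes: Layer
    breaks: np.ndarray
    k: int


def jenks_classify(layer: Layer, k: int = 5) -> ClassifiedSuitability:
    """Discretize a continuous layer into k natural-breaks classes.

    Ties at a break point are assigned to the lower class (breaks fall at
    midpoints between distinct values so exact ties cannot occur on data
    values, but the convention is enforced via right-open binning).
    """
    vals = layer.valid_values()
    breaks = jenks_breaks(vals, k)
    cls = np.full(layer.values.shape, np.nan)
    m = layer.valid_mask
    cls[m] = 1 + np.searchsorted(breaks, layer.values[m], side="left")
    return ClassifiedSuitability(Layer(layer.grid, cls), breaks, k)


@dataclass
class PseudoAbsenceSet:
    """Sampled pseudo-absence points with their generating class."""

    x: np.ndarray
    y: np.ndarray
    cell_class: np.ndarray
    seed: int | None

    def __len__(self) -> int:
        return self.x.size


def sample_pseudoabsences(
    classified: ClassifiedSuitability,
    n: int,
    allowed_classes: set[int] = frozenset({1, 2, 3}),
    seed: int | None = None,
    exclude_cells: np.ndarray | None = None,
    with_replacement: bool = False,
) -> PseudoAbsenceSet:
    """Sample n pseudo-absence points uniformly over low-suitability cells.

    Cells are drawn without replacement (by default) from the union of the
    allowed classes, then each point is jittered uniformly inside its cell.
    ``exclude_cells`` is a boolean mask (e.g. presence cells) removed from
    the eligible pool; the default workflow excludes presence cells.
    """
    cls = classified.classes
    eligible = np.isfinite(cls.values) & np.isin(cls.values, list(allowed_classes))
    if exclude_cells is not None:
        eligible &= ~exclude_cells
    rr, cc = np.nonzero(eligible)
    n_elig = rr.size
    if not with_replacement and n_elig < n:
        raise ValueError(
            f"only {n_elig} eligible cells for {n} pseudo-absences "
            f"(shortfall {n - n_elig}); pass with_replacement=True to allow reuse"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_elig, size=n, replace=with_replacement)
    g = cls.grid
    r, c = rr[idx], cc[idx]
    x = g.x_origin + (c + rng.random(n)) * g.cell_size
    y = g.y_top - (r + rng.random(n)) * g.cell_size
    return PseudoAbsenceSet(x, y, cls.values[r, c].astype(int), seed)
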