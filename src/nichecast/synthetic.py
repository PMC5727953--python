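"""Synthetic landscapes, species occurrences and pseudo-GCM scenarios.

Every downstream stage of the pipeline (screening, envelope profiling,
boosted-tree fitting, hindcasting, overlap tests) is testable without
external rasters because this module generates inputs with the statistical
structure the analysis assumes:

* spatially autocorrelated predictor layers built by Gaussian smoothing of
  white noise (optionally with a latitudinal gradient), with pairwise
  cross-layer correlations induced by linear mixing of orthonormalized
  fields against a target correlation matrix;
* presences drawn by Bernoulli acceptance sampling from a known smooth
  suitability function (a logistic link over weighted per-predictor
  responses), so the generating niche is available as ground truth;
* "pseudo-GCM" past scenarios made by shifting and scaling layers, with
  optionally a spatial gradient in the offset, so that some cells fall
  outside the reference range (non-analog climate) and extrapolation
  handling can be exercised.

All randomness flows from a single integer seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import GridSpec, Layer, OccurrenceSet, PredictorStack

__all__ = [
    "LayerSpec",
    "Response",
    "NicheDefinition",
    "ScenarioShift",
    "generate_landscape",
    "generate_occurrences",
    "make_scenario_variants",
    "true_suitability",
    "default_layer_specs",
    "preset_niche",
]


@dataclass(frozen=True)
class LayerSpec:
    """Recipe for one synthetic predictor layer.

    The layer is ``base + amplitude * field`` where ``field`` is a
    standardized spatial pattern combining smoothed white noise and an
    optional north-south gradient (``gradient_weight`` in units of the
    noise standard deviation; positive = increasing northward).
    """

    name: str
    base: float = 0.0
    amplitude: float = 1.0
    smooth_sigma: float = 3.0
    gradient_weight: float = 0.0


@dataclass(frozen=True)
class Response:
    """Smooth response of suitability to one predictor.

    direction: 'increasing', 'decreasing' or 'unimodal'; ``center`` and
    ``width`` are in predictor units; ``weight`` scales the contribution to
    the logit.  Monotone responses are scaled logistic ramps; unimodal is a
    Gaussian bump mapped to [-1, 1].
    """

    direction: str
    center: float = 0.0
    width: float = 1.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in {"increasing", "decreasing", "unimodal"}:
            raise ValueError(f"unknown response direction {self.direction!r}")
        if not np.isfinite(self.weight):
            raise ValueError("response weight must be finite")
        if self.width <= 0:
            raise ValueError("response width must be > 0")

    def contribution(self, v: np.ndarray) -> np.ndarray:
        z = (np.asarray(v, dtype=float) - self.center) / self.width
        if self.direction == "increasing":
            g = 2.0 * expit(z) - 1.0  # in (-1, 1), increasing
        elif self.direction == "decreasing":
            g = 1.0 - 2.0 * expit(z)
        else:
            g = 2.0 * np.exp(-0.5 * z * z) - 1.0
        return self.weight * g


@dataclass(frozen=True)
class NicheDefinition:
    """Known suitability function: logistic link over weighted responses."""

    species_id: str
    responses: Mapping[str, Response]
    intercept: float = 0.0

    def suitability(self, predictor_values: Mapping[str, np.ndarray]) -> np.ndarray:
        logit = None
        for name, resp in self.responses.items():
            c = resp.contribution(predictor_values[name])
            logit = c if logit is None else logit + c
        if logit is None:
            raise ValueError("niche has no responses")
        return expit(logit + self.intercept)


@dataclass(frozen=True)
class ScenarioShift:
    """Per-layer affine shift emulating one GCM's past-scenario divergence.

    ``new = factor * old + offset (+ offset_gradient * y_norm)`` where
    ``y_norm`` runs 0 at the southern edge to 1 at the northern edge.
    A zero-offset/unit-factor shift is the identity.
    """

    gcm_id: str
    offsets: Mapping[str, float] = field(default_factory=dict)
    factors: Mapping[str, float] = field(default_factory=dict)
    offset_gradients: Mapping[str, float] = field(default_factory=dict)


def generate_landscape(
    n_rows: int,
    n_cols: int,
    layer_specs: Sequence[LayerSpec],
    correlation_targets: Mapping[tuple[str, str], float] | None = None,
    seed: int | None = None,
    x_origin: float = 0.0,
    y_top: float | None = None,
    cell_size: float = 1.0,
) -> PredictorStack:
    """Generate a stack of spatially smooth, mutually correlated layers.

    ``correlation_targets`` maps layer-name pairs to target Pearson r in
    (-1, 1); unlisted pairs target 0.  The target matrix must be positive
    definite.  Achieved cell-wise correlations are exact up to the later
    amplitude/base transform because the underlying standardized patterns
    are orthonormalized before mixing through the Cholesky factor.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10x10")
    names = [s.name for s in layer_specs]
    if len(set(names)) != len(names):
        raise ValueError("layer names must be unique")
    k = len(names)
    rng = np.random.default_rng(seed)
    n_cells = n_rows * n_cols

    # standardized spatial patterns (smoothed noise + optional gradient)
    y_norm = np.linspace(1.0, 0.0, n_rows)[:, None] * np.ones((1, n_cols))
    patterns = np.empty((k, n_cells))
    flat_amp = np.zeros(k, dtype=bool)
    for i, spec in enumerate(layer_specs):
        noise = rng.standard_normal((n_rows, n_cols))
        f = gaussian_filter(noise, sigma=spec.smooth_sigma, mode="reflect")
        sd = f.std()
        f = f / sd if sd > 0 else f
        f = f + spec.gradient_weight * (y_norm - y_norm.mean())
        sd = f.std()
        if sd > 0:
            f = (f - f.mean()) / sd
        else:
            flat_amp[i] = True
        patterns[i] = f.ravel()

    if correlation_targets:
        target = np.eye(k)
        for (a, b), r in correlation_targets.items():
            if a not in names or b not in names:
                raise ValueError(f"unknown layer in correlation target: ({a}, {b})")
            if not (-1.0 < r < 1.0):
                raise ValueError(f"correlation target must be in (-1, 1), got {r}")
            ia, ib = names.index(a), names.index(b)
            target[ia, ib] = target[ib, ia] = r
        try:
            chol = np.linalg.cholesky(target)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation target matrix is not positive definite") from exc
        # orthonormalize patterns over cells, then mix: empirical corr == target
        q, _ = np.linalg.qr(patterns.T)  # n_cells x k, orthonormal columns
        mixed = (chol @ (q.T * np.sqrt(n_cells - 1)))
        patterns = mixed

    grid = GridSpec(
        x_origin=x_origin,
        y_top=float(n_rows * cell_size) if y_top is None else y_top,
        cell_size=cell_size,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    layers = {}
    for i, spec in enumerate(layer_specs):
        vals = spec.base + spec.amplitude * patterns[i].reshape(n_rows, n_cols)
        if spec.amplitude == 0:
            vals = np.full((n_rows, n_cols), float(spec.base))
        layers[spec.name] = Layer(grid, vals)
    return PredictorStack(layers)


def true_suitability(stack: PredictorStack, niche: NicheDefinition) -> Layer:
    """Evaluate the generating niche over every cell of the stack."""
    vals = {n: stack[n].values for n in niche.responses if n in stack}
    missing = [n for n in niche.responses if n not in stack]
    if missing:
        raise ValueError(f"stack lacks predictor(s) {missing} used by the niche")
    s = niche.suitability(vals)
    s = np.where(stack.valid_mask(), s, np.nan)
    return Layer(stack.grid, s)


def generate_occurrences(
    stack: PredictorStack,
    niche: NicheDefinition,
    n_points: int,
    seed: int | None = None,
    max_tries_factor: int = 10_000,
) -> OccurrenceSet:
    """Draw presences by Bernoulli acceptance from the true suitability.

    Candidate cells are drawn uniformly over valid cells; each candidate is
    accepted with probability equal to the niche's suitability there, until
    exactly ``n_points`` are accepted.  Points are jittered uniformly inside
    the accepted cell.  Errors on an all-nodata stack and on suitability
    that is (numerically) zero everywhere.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    suit = true_suitability(stack, niche)
    mask = stack.valid_mask()
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("stack has no valid cells")
    p = suit.values[rr, cc]
    if not np.any(p > 0):
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    xs, ys = [], []
    g = stack.grid
    max_tries = max_tries_factor * n_points
    tries = 0
    while len(xs) < n_points:
        m = min(4 * (n_points - len(xs)) + 16, 1_000_000)
        tries += m
        if tries > max_tries:
            raise RuntimeError("acceptance sampling failed to converge (suitability too low)")
        idx = rng.integers(0, rr.size, size=m)
        accept = rng.random(m) < p[idx]
        for i in idx[accept]:
            if len(xs) >= n_points:
                break
            r, c = rr[i], cc[i]
            xs.append(g.x_origin + (c + rng.random()) * g.cell_size)
            ys.append(g.y_top - (r + rng.random()) * g.cell_size)
    return OccurrenceSet(niche.species_id, np.array(xs), np.array(ys))


def make_scenario_variants(
    stack: PredictorStack, shifts: Sequence[ScenarioShift]
) -> dict[str, PredictorStack]:
    """Apply each pseudo-GCM shift to the stack; unshifted layers are copied."""
    out: dict[str, PredictorStack] = {}
    g = stack.grid
    y_norm = np.linspace(1.0, 0.0, g.n_rows)[:, None] * np.ones((1, g.n_cols))
    for shift in shifts:
        for name in list(shift.offsets) + list(shift.factors) + list(shift.offset_gradients):
            if name not in stack:
                raise ValueError(f"shift {shift.gcm_id!r} names unknown layer {name!r}")
        layers = {}
        for name, layer in stack.items():
            vals = layer.values.copy()
            fac = shift.factors.get(name, 1.0)
            off = shift.offsets.get(name, 0.0)
            grad = shift.offset_gradients.get(name, 0.0)
            vals = fac * vals + off + grad * y_norm
            layers[name] = Layer(g, vals)
        out[shift.gcm_id] = PredictorStack(layers)
    return out


def default_layer_specs() -> list[LayerSpec]:
    """Six-layer landscape emulating a screened bioclim stack.

    Units are nominal (temperature-like layers in tenths of degrees /
    degrees, precipitation-like in mm) so the generated ranges resemble the
    magnitudes of the standard bioclimatic variables.
    """
    return [
        LayerSpec("temp_range", base=25.0, amplitude=4.0, smooth_sigma=4.0, gradient_weight=1.0),
        LayerSpec("temp_seasonality", base=60.0, amplitude=12.0, smooth_sigma=4.0),
        LayerSpec("annual_precip", base=900.0, amplitude=250.0, smooth_sigma=4.0, gradient_weight=-0.5),
        LayerSpec("precip_dry_q", base=120.0, amplitude=45.0, smooth_sigma=4.0),
        LayerSpec("precip_cold_q", base=300.0, amplitude=90.0, smooth_sigma=4.0),
        LayerSpec("altitude", base=600.0, amplitude=350.0, smooth_sigma=5.0),
    ]


def default_correlation_targets() -> dict[tuple[str, str], float]:
    """Moderate cross-correlations typical of co-varying climate layers."""
    return {
        ("annual_precip", "precip_cold_q"): 0.6,
        ("precip_dry_q", "annual_precip"): 0.4,
        ("temp_range", "temp_seasonality"): 0.5,
    }


def preset_niche(which: str) -> NicheDefinition:
    """Two packaged niches with opposite responses on shared predictors.

    Species "montane" prefers low temperature range and high precipitation;
    species "lowland" prefers the opposite on the same two predictors, so
    the pair mimics parapatric species with opposite responses to the most
    contributing variables.  Both optima sit in the tails of the landscape
    distribution (response centers about 1.2 standard deviations from the
    layer means), giving restricted ranges with prevalence near 0.1 — the
    regime of narrowly distributed endemics for which envelope-profiled
    pseudo-absence selection is designed.
    """
    if which == "montane":
        return NicheDefinition(
            "montane",
            {
                "temp_range": Response("decreasing", center=20.0, width=1.5, weight=3.0),
                "annual_precip": Response("increasing", center=1200.0, width=100.0, weight=3.0),
                "precip_dry_q": Response("unimodal", center=140.0, width=60.0, weight=1.0),
            },
        )
    if which == "lowland":
        return NicheDefinition(
            "lowland",
            {
                "temp_range": Response("increasing", center=30.0, width=1.5, weight=3.0),
                "annual_precip": Response("decreasing", center=600.0, width=100.0, weight=3.0),
                "precip_cold_q": Response("unimodal", center=280.0, width=80.0, weight=1.0),
            },
        )
    raise ValueError(f"unknown preset {which!r} (use 'montane' or 'lowland')")
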