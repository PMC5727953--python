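"""Niche-overlap statistics and randomization tests.

Two complementary routes quantify how much two species' climatic niches
overlap.  The geographic route computes Schoener's D between the species'
suitability projections and compares it to null distributions built by
randomization: the equivalency test pools and repartitions the occurrences
(are the niches interchangeable?), while the background test replaces one
species' occurrences with random points from its available background (is
the observed overlap lower than expected from habitat availability alone?).
The environmental-space route ordinates the pooled background environment
onto two principal components, kernel-smooths occurrence and availability
densities on a gridded environmental space, and computes D between the
availability-corrected occupancies, with analogous permutation tests.

All tests are one-tailed toward low overlap: divergence is supported when
the observed D falls below the 5th percentile of the null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .envelope import BioclimEnvelope
from .grids import Layer, OccurrenceSet, PredictorStack, extract_values

logger = logging.getLogger("nichecast")

__all__ = [
    "OverlapResult",
    "EnvSpaceGrid",
    "DensityCurve",
    "schoener_d",
    "equivalency_test",
    "background_test",
    "env_space",
    "occurrence_density_curve",
]


def schoener_d(surface_a: Layer | np.ndarray, surface_b: Layer | np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |p_a - p_b| on normalized surfaces.

    Each surface is normalized to sum 1 over the shared valid cells, so D
    is invariant to positive rescaling; 1 = identical, 0 = disjoint.
    """
    a = surface_a.values if isinstance(surface_a, Layer) else np.asarray(surface_a, dtype=float)
    b = surface_b.values if isinstance(surface_b, Layer) else np.asarray(surface_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("surfaces must be co-registered (same shape)")
    valid = np.isfinite(a) & np.isfinite(b)
    av, bv = a[valid], b[valid]
    sa, sb = av.sum(), bv.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("each surface needs at least one positive cell")
    return float(1.0 - 0.5 * np.abs(av / sa - bv / sb).sum())


@dataclass
class OverlapResult:
    """Observed D, its randomization null, and the one-tailed decision."""

    d_observed: float
    null: np.ndarray
    kind: str
    p: float
    percentile_5: float
    percentile_95: float
    randomized: str = ""  # which species' points were randomized (directional tests)
    n_skipped: int = 0

    @classmethod
    def from_null(cls, d_obs: float, null: np.ndarray, kind: str, randomized: str = "",
                  n_skipped: int = 0) -> "OverlapResult":
        null = np.asarray(null, dtype=float)
        # add-one rule: p can never be exactly 0
        p = (1 + int(np.sum(null <= d_obs))) / (1 + null.size)
        return cls(
            d_observed=d_obs,
            null=null,
            kind=kind,
            p=float(p),
            percentile_5=float(np.percentile(null, 5)),
            percentile_95=float(np.percentile(null, 95)),
            randomized=randomized,
            n_skipped=n_skipped,
        )

    @property
    def rejects_at_5pct(self) -> bool:
        """Divergence supported: observed D below the null's 5th percentile."""
        return self.d_observed < self.percentile_5


ModelSpec = Callable[[pd.DataFrame], "object"]


def _default_model_spec(presence_frame: pd.DataFrame):
    return BioclimEnvelope().fit(presence_frame)


def _fit_and_project(
    x: np.ndarray, y: np.ndarray, stack: PredictorStack, model_spec: ModelSpec | None
) -> Layer:
    sm = extract_values(stack, x, y)
    spec = model_spec or _default_model_spec
    model = spec(sm.frame)
    if hasattr(model, "score_stack"):
        return model.score_stack(stack)
    # generic fallback: model exposes project()-like behaviour
    from .sdm import project as sdm_project  # local import avoids cycle

    return sdm_project(model, stack).suitability


def equivalency_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    stack: PredictorStack,
    model_spec: ModelSpec | None = None,
    n_reps: int = 100,
    seed: int | None = None,
) -> OverlapResult:
    """Niche equivalency by pooled-repartition randomization.

    The observed D comes from models fitted to the true occurrence sets.
    Each replicate pools all points, randomly repartitions them into sets
    of the original sizes, refits both models, projects, and recomputes D.
    Equivalency is rejected when the observed D falls below the null's 5th
    percentile.
    """
    if len(occ_a) == 0 or len(occ_b) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    pa = _fit_and_project(occ_a.x, occ_a.y, stack, model_spec)
    pb = _fit_and_project(occ_b.x, occ_b.y, stack, model_spec)
    d_obs = schoener_d(pa, pb)
    rng = np.random.default_rng(seed)
    all_x = np.concatenate([occ_a.x, occ_b.x])
    all_y = np.concatenate([occ_a.y, occ_b.y])
    na = len(occ_a)
    null, skipped = [], 0
    for _ in range(n_reps):
        perm = rng.permutation(all_x.size)
        for attempt in range(2):
            try:
                la = _fit_and_project(all_x[perm[:na]], all_y[perm[:na]], stack, model_spec)
                lb = _fit_and_project(all_x[perm[na:]], all_y[perm[na:]], stack, model_spec)
                null.append(schoener_d(la, lb))
                break
            except Exception as exc:  # refit failure: retry once with a new split
                if attempt == 1:
                    logger.warning("equivalency replicate skipped: %s", exc)
                    skipped += 1
                else:
                    perm = rng.permutation(all_x.size)
    return OverlapResult.from_null(d_obs, np.asarray(null), "equivalency", n_skipped=skipped)


def background_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    background_b: np.ndarray,
    stack: PredictorStack,
    model_spec: ModelSpec | None = None,
    n_reps: int = 100,
    seed: int | None = None,
) -> OverlapResult:
    """Background (similarity) test: A's observed niche vs B's availability.

    ``background_b`` is a boolean cell mask of species B's background
    region.  Each replicate draws ``len(occ_b)`` random points from that
    region, fits a model to them, and computes D against species A's
    observed model.  The test is directional; the result records which
    species' background was randomized.
    """
    if len(occ_a) == 0 or len(occ_b) == 0:
        raise ValueError("both occurrence sets must be non-empty")
    g = stack.grid
    rr, cc = np.nonzero(np.asarray(background_b, dtype=bool) & stack.valid_mask())
    nb = len(occ_b)
    if rr.size == 0:
        raise ValueError("background region is empty")
    if rr.size < nb:
        logger.warning(
            "background region has %d cells for %d points; cells will repeat", rr.size, nb
        )
    pa = _fit_and_project(occ_a.x, occ_a.y, stack, model_spec)
    pb = _fit_and_project(occ_b.x, occ_b.y, stack, model_spec)
    d_obs = schoener_d(pa, pb)
    rng = np.random.default_rng(seed)
    null, skipped = [], 0
    for _ in range(n_reps):
        for attempt in range(2):
            idx = rng.choice(rr.size, size=nb, replace=True)
            x = g.x_origin + (cc[idx] + rng.random(nb)) * g.cell_size
            y = g.y_top - (rr[idx] + rng.random(nb)) * g.cell_size
            try:
                lb = _fit_and_project(x, y, stack, model_spec)
                null.append(schoener_d(pa, lb))
                break
            except Exception as exc:
                if attempt == 1:
                    logger.warning("background replicate skipped: %s", exc)
                    skipped += 1
    return OverlapResult.from_null(
        d_obs, np.asarray(null), "background", randomized=occ_b.species_id, n_skipped=skipped
    )


# ---------------------------------------------------------------------------
# Environmental-space (ordination) route


@dataclass
class EnvSpaceGrid:
    """Gridded two-axis environmental space with per-species densities."""

    pca: PCA
    axis1: np.ndarray  # grid coordinates along PC1 (length R)
    axis2: np.ndarray
    occurrence: dict[str, np.ndarray]  # R x R, sums to 1
    availability: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]  # corrected o/e, normalized
    occupancy_uncorrected: dict[str, np.ndarray]
    d_env: float
    equivalency: OverlapResult | None = None
    similarity: dict[str, OverlapResult] = field(default_factory=dict)


def _kde_on_grid(points: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                 bandwidth_rule: str) -> np.ndarray:
    kde = gaussian_kde(points.T, bw_method=bandwidth_rule)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(len(xs), len(ys))
    total = dens.sum()
    if total <= 0:
        raise ValueError("degenerate kernel density")
    return dens / total


def _occupancy(o: np.ndarray, e: np.ndarray, corrected: bool) -> np.ndarray:
    if not corrected:
        return o / o.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(e > 0, o / e, 0.0)
    s = z.sum()
    if s <= 0:
        raise ValueError("occupancy grid is identically zero")
    return z / s


def env_space(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    background_a: np.ndarray,
    background_b: np.ndarray,
    stack: PredictorStack,
    R: int = 100,
    bandwidth_rule: str = "scott",
    n_reps: int = 100,
    seed: int | None = None,
    corrected: bool = True,
    run_tests: bool = True,
) -> EnvSpaceGrid:
    """Niche overlap in ordinated environmental space.

    Principal components are fitted on the pooled background environment
    (both species' background cells); occurrence and availability scores
    are kernel-smoothed on an R x R grid spanning the pooled background.
    Occupancy is the availability-corrected density o/e (cells with no
    availability set to 0), normalized to sum 1; D is Schoener's D between
    occupancies.  Equivalency randomizes occurrence labels; similarity
    redraws one species' occurrences from its own background.
    """
    for occ in (occ_a, occ_b):
        if len(occ) < 5:
            raise ValueError("need at least 5 occurrences per species")
    bg_frames = []
    bg_scores = {}
    for sid, bg in (("a", background_a), ("b", background_b)):
        rr, cc = np.nonzero(np.asarray(bg, dtype=bool) & stack.valid_mask())
        if rr.size == 0:
            raise ValueError(f"background {sid!r} is empty")
        frame = pd.DataFrame({n: stack[n].values[rr, cc] for n in stack.names})
        bg_frames.append(frame)
    pooled = pd.concat(bg_frames, ignore_index=True)
    if (pooled.std(axis=0) == 0).all():
        raise ValueError("degenerate ordination: pooled background has zero variance")
    pca = PCA(n_components=2)
    pca.fit(pooled.to_numpy(dtype=float))
    if np.any(pca.explained_variance_ <= 0):
        raise ValueError("degenerate ordination: zero-variance principal component")

    def scores(frame: pd.DataFrame) -> np.ndarray:
        return pca.transform(frame[pooled.columns].to_numpy(dtype=float))

    bg_sc = {"a": scores(bg_frames[0]), "b": scores(bg_frames[1])}
    occ_sc = {
        "a": scores(extract_values(stack, occ_a.x, occ_a.y).frame),
        "b": scores(extract_values(stack, occ_b.x, occ_b.y).frame),
    }
    all_bg = np.vstack([bg_sc["a"], bg_sc["b"]])
    xs = np.linspace(all_bg[:, 0].min(), all_bg[:, 0].max(), R)
    ys = np.linspace(all_bg[:, 1].min(), all_bg[:, 1].max(), R)

    # availability densities never change across replicates: compute once
    e_grid = {
        "a": _kde_on_grid(bg_sc["a"], xs, ys, bandwidth_rule),
        "b": _kde_on_grid(bg_sc["b"], xs, ys, bandwidth_rule),
    }

    def occupancy_of(occ_pts: np.ndarray, which_bg: str) -> tuple[np.ndarray, ...]:
        o = _kde_on_grid(occ_pts, xs, ys, bandwidth_rule)
        e = e_grid[which_bg]
        return o, e, _occupancy(o, e, corrected), _occupancy(o, e, False)

    oa, ea, za, za_u = occupancy_of(occ_sc["a"], "a")
    ob, eb, zb, zb_u = occupancy_of(occ_sc["b"], "b")
    d_obs = schoener_d(za, zb)

    result = EnvSpaceGrid(
        pca=pca,
        axis1=xs,
        axis2=ys,
        occurrence={occ_a.species_id: oa, occ_b.species_id: ob},
        availability={occ_a.species_id: ea, occ_b.species_id: eb},
        occupancy={occ_a.species_id: za, occ_b.species_id: zb},
        occupancy_uncorrected={occ_a.species_id: za_u, occ_b.species_id: zb_u},
        d_env=d_obs,
    )
    if not run_tests:
        return result

    rng = np.random.default_rng(seed)
    pooled_occ = np.vstack([occ_sc["a"], occ_sc["b"]])
    na = occ_sc["a"].shape[0]
    null_eq = []
    for _ in range(n_reps):
        perm = rng.permutation(pooled_occ.shape[0])
        _, _, z1, _ = occupancy_of(pooled_occ[perm[:na]], "a")
        _, _, z2, _ = occupancy_of(pooled_occ[perm[na:]], "b")
        null_eq.append(schoener_d(z1, z2))
    result.equivalency = OverlapResult.from_null(d_obs, np.asarray(null_eq), "env_equivalency")

    for sid, occ_id, other_z in (
        ("a", occ_a.species_id, zb),
        ("b", occ_b.species_id, za),
    ):
        bg = bg_sc[sid]
        n_occ = occ_sc[sid].shape[0]
        null_sim = []
        for _ in range(n_reps):
            idx = rng.choice(bg.shape[0], size=n_occ, replace=True)
            _, _, z_rand, _ = occupancy_of(bg[idx], sid)
            null_sim.append(schoener_d(z_rand, other_z))
        result.similarity[occ_id] = OverlapResult.from_null(
            d_obs, np.asarray(null_sim), "env_similarity", randomized=occ_id
        )
    return result


@dataclass
class DensityCurve:
    """Kernel-smoothed occurrence density along one predictor."""

    predictor: str
    grid: np.ndarray
    density: np.ndarray  # integrates to 1 over the grid

    def mass_in(self, lo: float, hi: float) -> float:
        sel = (self.grid >= lo) & (self.grid <= hi)
        return float(np.trapezoid(np.where(sel, self.density, 0.0), self.grid))


def occurrence_density_curve(
    occ: OccurrenceSet, stack: PredictorStack, predictor: str, grid_n: int = 512
) -> DensityCurve:
    """Gaussian-kernel density of a predictor's values at the occurrences.

    The evaluation grid spans the predictor layer's full valid range and
    the density is renormalized to integrate to 1 over that grid.  The
    bandwidth follows the standard normal-reference (Scott) rule.
    """
    if len(occ) < 5:
        raise ValueError("need at least 5 occurrences")
    if predictor not in stack:
        raise ValueError(f"unknown predictor {predictor!r}")
    vals = extract_values(stack, occ.x, occ.y).frame[predictor].to_numpy(dtype=float)
    layer_vals = stack[predictor].valid_values()
    grid = np.linspace(layer_vals.min(), layer_vals.max(), grid_n)
    if np.ptp(vals) == 0:
        logger.warning(
            "occurrence_density_curve: zero-variance values; density is a spike at %g", vals[0]
        )
        dens = np.zeros(grid_n)
        dens[int(np.argmin(np.abs(grid - vals[0])))] = 1.0
        dens /= np.trapezoid(dens, grid)
        return DensityCurve(predictor, grid, dens)
    kde = gaussian_kde(vals, bw_method="scott")
    dens = kde(grid)
    dens /= np.trapezoid(dens, grid)
    return DensityCurve(predictor, grid, dens)
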