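"""Forward stepwise discriminant function analysis over zone classes.

Given climate samples labelled by range zone (allopatric area of species A,
sympatric area, allopatric area of species B), predictors are entered one
at a time: at each step the candidate minimizing Wilks' Lambda enters,
admitted only if its partial F exceeds the p-to-enter criterion.  Canonical
variates come from the eigen-decomposition of within^-1 * between scatter
on the entered predictors.  Classification uses linear discriminant scores
with a pooled covariance and equal priors; the classification matrix is
reported with per-class percent correct, their unweighted mean ("total"
percent, matching the usual stepwise-DFA report convention) and the pooled
percent, both labelled.

No standardization or normalization of the predictors is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "StepwiseDiscriminant",
    "ClassificationMatrix",
    "stepwise_dfa",
    "classify",
    "classification_matrix_from_counts",
]


def _scatter(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class and total scatter (cross-product) matrices."""
    mean = X.mean(axis=0)
    t = (X - mean).T @ (X - mean)
    w = np.zeros_like(t)
    for g in np.unique(labels):
        xg = X[labels == g]
        w += (xg - xg.mean(axis=0)).T @ (xg - xg.mean(axis=0))
    return w, t


def _wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    w, t = _scatter(X, labels)
    sign_w, ld_w = np.linalg.slogdet(w)
    sign_t, ld_t = np.linalg.slogdet(t)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(ld_w - ld_t))


class StepwiseDiscriminant(BaseEstimator, ClassifierMixin):
    """Forward stepwise linear discriminant analysis.

    Parameters
    ----------
    p_enter : significance threshold on the partial F for a candidate to
        enter, default 0.05.

    Fitted attributes: ``selected_`` (entry order), ``steps_`` (frame with
    per-step F-to-enter, p-level and Wilks' Lambda — the entry trail),
    ``coefficients_`` (linear discriminant coefficients per class),
    ``canonical_axes_`` and ``canonical_eigenvalues_``.
    """

    def __init__(self, p_enter: float = 0.05):
        self.p_enter = p_enter

    def fit(self, X, y) -> "StepwiseDiscriminant":
        frame = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = self.classes_.size
        if k < 2:
            raise ValueError("need at least 2 classes")
        n = len(frame)
        cols = list(frame.columns)
        Xv = frame.to_numpy(dtype=float)

        selected: list[int] = []
        trail = []
        lambda_prev = 1.0
        while True:
            best = None
            for j in range(len(cols)):
                if j in selected:
                    continue
                sub = Xv[:, selected + [j]]
                try:
                    lam = _wilks_lambda(sub, y)
                except np.linalg.LinAlgError:
                    continue
                if best is None or lam < best[1]:
                    best = (j, lam)
            if best is None:
                break
            j, lam = best
            s = len(selected)
            df1 = k - 1
            df2 = n - k - s
            if df2 <= 0:
                break
            f_enter = (df2 / df1) * (lambda_prev / lam - 1.0)
            p_level = float(f_dist.sf(f_enter, df1, df2))
            if p_level >= self.p_enter or lam >= lambda_prev:
                break
            selected.append(j)
            trail.append(
                {"variable": cols[j], "F_to_enter": float(f_enter),
                 "p_level": p_level, "wilks_lambda": lam}
            )
            lambda_prev = lam
        if not selected:
            raise ValueError("no predictor met the entry criterion")
        self.selected_ = [cols[j] for j in selected]
        self.steps_ = pd.DataFrame(trail)

        Xs = Xv[:, selected]
        w, t = _scatter(Xs, y)
        b = t - w
        if np.linalg.matrix_rank(w) < w.shape[0]:
            raise np.linalg.LinAlgError(
                f"singular within-class scatter for predictors {self.selected_}"
            )
        # canonical variates: eigenvectors of W^-1 B, ordered by eigenvalue
        evals, evecs = np.linalg.eig(np.linalg.solve(w, b))
        order = np.argsort(evals.real)[::-1]
        n_axes = min(k - 1, len(selected))
        self.canonical_eigenvalues_ = evals.real[order][:n_axes]
        self.canonical_axes_ = evecs.real[:, order][:, :n_axes]

        # linear discriminant scores: pooled covariance, equal priors
        pooled = w / (n - k)
        self._pooled_inv_ = np.linalg.inv(pooled)
        self._means_ = {g: Xs[y == g].mean(axis=0) for g in self.classes_}
        return self

    def decision_scores(self, X) -> pd.DataFrame:
        frame = pd.DataFrame(X)
        missing = [c for c in self.selected_ if c not in frame.columns]
        if missing:
            raise ValueError(f"missing predictor(s): {missing}")
        Xs = frame[self.selected_].to_numpy(dtype=float)
        scores = {}
        for g in self.classes_:
            m = self._means_[g]
            a = self._pooled_inv_ @ m
            scores[g] = Xs @ a - 0.5 * m @ a
        return pd.DataFrame(scores)

    def predict(self, X) -> np.ndarray:
        sc = self.decision_scores(X)
        winners = sc.to_numpy().argmax(axis=1)
        return np.asarray([sc.columns[i] for i in winners])

    def transform(self, X) -> np.ndarray:
        """Canonical variate scores of the samples."""
        frame = pd.DataFrame(X)
        Xs = frame[self.selected_].to_numpy(dtype=float)
        return (Xs - Xs.mean(axis=0)) @ self.canonical_axes_


@dataclass
class ClassificationMatrix:
    """k x k count matrix (rows observed, columns predicted) plus percents."""

    counts: pd.DataFrame
    per_class_percent: pd.Series  # 100 * diagonal / row sum
    total_percent_unweighted: float  # mean of per-class percents
    total_percent_pooled: float  # 100 * trace / grand total

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ClassificationMatrix":
        counts = counts.astype(int)
        row_sums = counts.sum(axis=1)
        if (row_sums <= 0).any():
            raise ValueError("every observed class needs at least one sample")
        diag = pd.Series(np.diag(counts.to_numpy()), index=counts.index)
        per_class = 100.0 * diag / row_sums
        return cls(
            counts=counts,
            per_class_percent=per_class.round(1),
            total_percent_unweighted=round(float(per_class.mean()), 1),
            total_percent_pooled=round(100.0 * float(diag.sum()) / float(row_sums.sum()), 1),
        )


def classification_matrix_from_counts(counts) -> ClassificationMatrix:
    """Percent summaries from a printed/observed count matrix.

    ``counts`` may be a DataFrame, a nested list, or a dict of rows; rows
    are observed classes, columns predicted classes in the same order.
    """
    frame = pd.DataFrame(counts)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError("classification matrix must be square")
    return ClassificationMatrix.from_counts(frame)


def stepwise_dfa(samples: pd.DataFrame, labels, p_enter: float = 0.05) -> StepwiseDiscriminant:
    return StepwiseDiscriminant(p_enter=p_enter).fit(samples, labels)


def classify(dfa: StepwiseDiscriminant, samples: pd.DataFrame, labels) -> ClassificationMatrix:
    """Classification matrix of true vs predicted zone labels."""
    labels = np.asarray(labels)
    pred = dfa.predict(samples)
    classes = list(dfa.classes_)
    counts = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(labels, pred):
        counts.loc[t, p] += 1
    return ClassificationMatrix.from_counts(counts)
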