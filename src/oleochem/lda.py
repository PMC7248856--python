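"""Fisher linear discriminant analysis at selected wavenumbers.

Classification rule: nearest class mean in the Mahalanobis metric of the
pooled within-class covariance, equal priors.  Canonical axes come from the
generalized eigenproblem of the between-class scatter against the pooled
within-class scatter and provide the 2-D similarity-map coordinates.
Leave-one-out cross-validation refits the model once per held-out sample and
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .spectra import SampleMeta, SpectrumSet

__all__ = [
    "FeatureTable",
    "LDAModel",
    "ConfusionMatrix",
    "extract_features",
    "group_label",
    "lda_fit",
    "lda_predict",
    "loo_cross_validate",
]


@dataclass(frozen=True)
class FeatureTable:
    """Sample-by-feature matrix with one group label per row."""

    X: np.ndarray
    labels: tuple
    feature_names: tuple = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature table contains non-finite values")
        if len(self.labels) != X.shape[0]:
            raise ValueError("one label per row required")
        groups, counts = np.unique(np.asarray(self.labels), return_counts=True)
        if groups.size < 2:
            raise ValueError("at least two groups required")
        small = [f"{g} (n={c})" for g, c in zip(groups, counts) if c < 2]
        if small:
            raise ValueError(f"every group needs >= 2 samples; too small: {', '.join(small)}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def groups(self) -> tuple:
        return tuple(sorted(set(self.labels)))

    def drop(self, i: int) -> "FeatureTable":
        keep = np.arange(self.X.shape[0]) != i
        return FeatureTable(self.X[keep], tuple(np.asarray(self.labels)[keep]),
                            self.feature_names)


@dataclass(frozen=True)
class LDAModel:
    groups: tuple
    class_means: np.ndarray        # (G, p)
    pooled_cov: np.ndarray         # (p, p)
    priors: np.ndarray             # (G,)
    discriminant_axes: np.ndarray  # (p, m), m <= min(G-1, p)
    grand_mean: np.ndarray         # (p,)


@dataclass(frozen=True)
class ConfusionMatrix:
    groups: tuple
    counts: np.ndarray  # (G, G) ints, rows = true group

    @property
    def percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return 100.0 * self.counts / totals

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.groups), columns=list(self.groups))


def group_label(meta: SampleMeta) -> str:
    """Screen group name: 'CAO' for the pure oil, 'RSO<v>%' for blends."""
    v = meta.blend_fraction_v
    return "CAO" if v == 0 else f"RSO{v:g}%"


def extract_features(sset: SpectrumSet, wavenumbers, labeler=group_label) -> FeatureTable:
    """Absorbance at the grid point nearest each requested wavenumber."""
    grid = sset.grid
    idx = [int(np.argmin(np.abs(grid - w))) for w in wavenumbers]
    X = sset.to_matrix()[:, idx]
    labels = tuple(labeler(s.meta) for s in sset)
    return FeatureTable(X, labels, feature_names=tuple(float(grid[i]) for i in idx))


def _pooled_covariance(X: np.ndarray, labels: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    p = X.shape[1]
    means = np.zeros((len(groups), p))
    pooled = np.zeros((p, p))
    n = X.shape[0]
    for gi, g in enumerate(groups):
        Xg = X[labels == g]
        means[gi] = Xg.mean(axis=0)
        d = Xg - means[gi]
        pooled += d.T @ d
    pooled /= n - len(groups)
    return means, pooled


def lda_fit(features: FeatureTable, regularize: bool = True) -> LDAModel:
    """Fit class means, pooled within-class covariance and canonical axes.

    A small ridge (1e-8 x mean diagonal) is added only when the pooled
    covariance is numerically ill-conditioned; a singular covariance without
    ``regularize`` raises with a hint.
    """
    X = features.X
    labels = np.asarray(features.labels)
    groups = features.groups
    n, p = X.shape
    if n <= len(groups):
        raise ValueError("need more samples than groups")
    means, pooled = _pooled_covariance(X, labels, groups)
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e10:
        if not regularize:
            raise ValueError(
                f"pooled within-class covariance is singular/ill-conditioned (cond={cond:.2e});"
                " enable regularize=True"
            )
        pooled = pooled + (1e-8 * np.trace(pooled) / p) * np.eye(p)

    grand = X.mean(axis=0)
    Sb = np.zeros((p, p))
    for gi, g in enumerate(groups):
        ng = int((labels == g).sum())
        d = (means[gi] - grand)[:, None]
        Sb += ng * (d @ d.T)
    m = min(len(groups) - 1, p)
    evals, evecs = eigh(Sb, pooled)
    order = np.argsort(evals)[::-1][:m]
    axes = evecs[:, order]
    for j in range(axes.shape[1]):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] *= -1.0
    priors = np.full(len(groups), 1.0 / len(groups))
    return LDAModel(groups=groups, class_means=means, pooled_cov=pooled,
                    priors=priors, discriminant_axes=axes, grand_mean=grand)


def lda_predict(model: LDAModel, X) -> tuple[list[str], np.ndarray]:
    """Nearest-class-mean labels in the Mahalanobis metric plus canonical
    scores on the first two discriminant axes.

    Ties in distance break toward the lexicographically first group label
    (groups are stored sorted)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    p = model.class_means.shape[1]
    if X.shape[1] != p:
        raise ValueError(f"feature dimension {X.shape[1]} does not match model ({p})")
    chol = cho_factor(model.pooled_cov)
    d2 = np.empty((X.shape[0], len(model.groups)))
    for gi in range(len(model.groups)):
        diff = X - model.class_means[gi]
        d2[:, gi] = np.einsum("ij,ij->i", diff, cho_solve(chol, diff.T).T)
    # argmin returns the first (lexicographically smallest) group on ties
    labels = [model.groups[i] for i in np.argmin(np.round(d2, 12), axis=1)]
    n_axes = min(2, model.discriminant_axes.shape[1])
    scores = (X - model.grand_mean) @ model.discriminant_axes[:, :n_axes]
    return labels, scores


def _confusion(groups, true_labels, pred_labels) -> ConfusionMatrix:
    gi = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[gi[t], gi[p]] += 1
    return ConfusionMatrix(groups=tuple(groups), counts=counts)


def loo_cross_validate(features: FeatureTable,
                       regularize: bool = True) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Leave-one-out cross-validated and resubstitution confusion matrices."""
    labels = np.asarray(features.labels)
    groups, counts = np.unique(labels, return_counts=True)
    small = [f"{g} (n={c})" for g, c in zip(groups, counts) if c < 3]
    if small:
        raise ValueError(f"leave-one-out needs >= 3 samples per group; too small: {', '.join(small)}")
    model = lda_fit(features, regularize=regularize)
    resub_pred, _ = lda_predict(model, features.X)
    cv_pred = []
    for i in range(features.X.shape[0]):
        sub = lda_fit(features.drop(i), regularize=regularize)
        pred, _ = lda_predict(sub, features.X[i])
        cv_pred.append(pred[0])
    g = model.groups
    return _confusion(g, features.labels, cv_pred), _confusion(g, features.labels, resub_pred)
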