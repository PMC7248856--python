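"""Principal component analysis for spectral exploration and wavenumber selection.

Mean-centred SVD with a deterministic sign convention (the largest-magnitude
element of every loading is positive).  Spectra share units, so no variance
scaling is applied.  Influential wavenumbers are picked as separated local
maxima of the explained-variance-weighted absolute loadings of the first
three components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import RegionSpec, SpectrumSet, crop_set

__all__ = [
    "PCAResult",
    "SelectedWavenumbers",
    "SELECTED_WAVENUMBERS",
    "pca_fit",
    "explained_variance_profile",
    "select_wavenumbers_from_loadings",
]

#: The seven diagnostic wavenumbers (cm^-1) used by the discriminant screen:
#: ester C=O stretch, CH2/CH3 bending, CH3 bending, three C-O/CH2 bands in
#: the 1160-1096 cm^-1 ester region and the cis CH=CH out-of-plane rock.
SELECTED_WAVENUMBERS = (1744.0, 1464.0, 1377.0, 1155.0, 1119.0, 1096.0, 721.0)


@dataclass(frozen=True)
class PCAResult:
    mean_vector: np.ndarray          # (p,)
    loadings: np.ndarray             # (p, k) orthonormal columns
    scores: np.ndarray               # (n, k)
    explained_var_pct: np.ndarray    # (k,) percentages of total variance

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class SelectedWavenumbers:
    wavenumbers: tuple   # picked centers, sorted by descending magnitude
    scores: tuple        # combined |loading| magnitude per pick


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        return data.to_matrix()
    return np.asarray(data, dtype=np.float64)


def pca_fit(data, n_components: int) -> PCAResult:
    """Column-mean centring followed by SVD of the centred matrix.

    ``explained_var_pct[i] = 100 * sigma_i^2 / sum_j sigma_j^2`` so the
    percentages over all min(n-1, p) components sum to 100.
    """
    X = _as_matrix(data)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with at least 2 samples")
    n, p = X.shape
    max_k = min(n - 1, p)
    if not 1 <= n_components <= max_k:
        raise ValueError(f"n_components={n_components} must lie in [1, {max_k}] for a {n}x{p} matrix")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    svals, vt = svals[:max_k], vt[:max_k]
    var = svals**2
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance: all samples identical")
    loadings = vt[:n_components].T.copy()
    # deterministic sign: largest-|element| of each loading made positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = Xc @ loadings
    return PCAResult(
        mean_vector=mean,
        loadings=loadings,
        scores=scores,
        explained_var_pct=100.0 * var[:n_components] / total,
    )


def explained_variance_profile(data: SpectrumSet, regions, n_components: int) -> pd.DataFrame:
    """One PCA per spectral region on identically preprocessed data; rows
    keyed by region label with per-component explained variance in %."""
    rows = []
    for region in regions:
        if not isinstance(region, RegionSpec):
            region = RegionSpec(tuple(region))
        res = pca_fit(crop_set(data, region), n_components)
        for i, pct in enumerate(res.explained_var_pct, start=1):
            rows.append({"region": region.label, "component": i, "explained_var_pct": float(pct)})
    return pd.DataFrame(rows)


def select_wavenumbers_from_loadings(result: PCAResult, grid: np.ndarray, k: int,
                                     min_separation: float = 10.0) -> SelectedWavenumbers:
    """Pick the ``k`` most influential wavenumbers from the loading spectra.

    The first (up to three) components' absolute loadings are combined with
    explained-variance weights; local maxima of the combined magnitude are
    picked greedily in order of decreasing magnitude while enforcing
    ``min_separation`` cm^-1 between picks.  Magnitude ties break toward the
    higher wavenumber.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size != result.loadings.shape[0]:
        raise ValueError("grid length does not match the number of loading rows")
    m = min(3, result.n_components)
    w = result.explained_var_pct[:m]
    w = w / w.sum()
    combined = np.abs(result.loadings[:, :m]) @ w

    # interior local maxima (plateaus resolved toward the higher wavenumber,
    # i.e. the lower index of the descending grid)
    cand = [i for i in range(1, combined.size - 1)
            if combined[i] >= combined[i - 1] and combined[i] > combined[i + 1]]
    # order by magnitude desc, ties toward higher wavenumber
    cand.sort(key=lambda i: (-combined[i], -grid[i]))
    picks: list[int] = []
    for i in cand:
        if all(abs(grid[i] - grid[j]) >= min_separation for j in picks):
            picks.append(i)
        if len(picks) == k:
            break
    if len(picks) < k:
        found = ", ".join(f"{grid[i]:g}" for i in picks)
        raise ValueError(
            f"only {len(picks)} separated loading maxima found (requested {k}): {found}"
        )
    return SelectedWavenumbers(
        wavenumbers=tuple(float(grid[i]) for i in picks),
        scores=tuple(float(combined[i]) for i in picks),
    )
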