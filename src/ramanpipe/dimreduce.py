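"""PCA fitting, projection, and explained-variance reporting.

Thin, deterministic wrapper around scikit-learn's full-SVD PCA that keeps
exactly the state the pipelines need (mean, components, variance ratios) and
produces the cumulative-explained-variance table used to pick the score-space
dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PCAState", "fit_pca", "transform_pca", "variance_table"]


@dataclass(frozen=True)
class PCAState:
    """Fitted PCA: feature mean, component rows, per-component variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    source_region: str = "full"

    def __post_init__(self) -> None:
        r = np.asarray(self.explained_variance_ratio)
        if np.any(r < -1e-12) or np.any(np.diff(r) > 1e-9):
            raise ValueError("variance ratios must be non-negative and non-increasing")
        if r.sum() > 1 + 1e-9:
            raise ValueError("cumulative explained variance ratio exceeds 1")

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.components.shape[1])

    @property
    def cumulative_ratio(self) -> float:
        return float(self.explained_variance_ratio.sum())


def fit_pca(matrix: np.ndarray, n_components: int, source_region: str = "full") -> PCAState:
    """Mean-centered PCA via deterministic full SVD, components by decreasing variance."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if not 1 <= n_components <= min(n, p):
        raise ValueError(f"n_components must be in [1, {min(n, p)}], got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(matrix)
    return PCAState(
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        source_region=source_region,
    )


def transform_pca(state: PCAState, matrix: np.ndarray) -> np.ndarray:
    """Project spectra onto the fitted components: (x - mean) @ components.T."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[-1] != state.n_features:
        raise ValueError(f"expected {state.n_features} features, got {matrix.shape[-1]}")
    return (matrix - state.mean) @ state.components.T


def variance_table(matrix: np.ndarray, component_counts: list[int] | None = None) -> pd.DataFrame:
    """Cumulative explained variance (%) for a ladder of component counts.

    One full-rank-limited fit covers all requested counts because PCA
    subspaces are nested.  Percentages are reported to one decimal; the raw
    values are kept in a second column.
    """
    counts = sorted(component_counts or [10, 20, 30, 40])
    matrix = np.asarray(matrix, dtype=float)
    state = fit_pca(matrix, max(counts))
    cum = np.cumsum(state.explained_variance_ratio) * 100.0
    rows = [
        {
            "n_components": k,
            "cumulative_explained_variance_pct": round(float(cum[k - 1]), 1),
            "raw_pct": float(cum[k - 1]),
        }
        for k in counts
    ]
    return pd.DataFrame(rows)
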