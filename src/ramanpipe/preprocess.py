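"""Spectral preprocessing operators and pipeline composition.

Operators
---------
``snip_baseline``
    Statistics-sensitive nonlinear iterative peak clipping: the autofluorescence
    background under each spectrum is estimated by repeatedly clipping every
    point to the average of its neighbours at growing window half-widths
    m = 1..iterations; the clipped curve is the baseline and the corrected
    spectrum is the residual.  Optional LLS dynamic-range compression
    v = ln(ln(sqrt(y+1)+1)+1) is available for count-scale data; it is off by
    default because on moderate intensity scales its curvature makes the
    clipping eat sloped backgrounds.
``l2_normalize`` / ``snv_normalize``
    Per-spectrum intensity normalization: division by the Euclidean norm, or
    standard-normal-variate centering/scaling (population standard deviation).
``median_filter`` / ``smooth``
    Impulse-noise removal (sliding median, mirror padding) and Savitzky-Golay
    or Gaussian smoothing.

Pipelines are ordered stage lists (:class:`PipelineSpec`): per-spectrum stages
run on the full grid, then the wavenumber region is selected, then PCA (the
only *fitted* stage) reduces dimensionality.  Named presets cover the main
study pipeline for classical classifiers (``suggested_ml``), the shorter one used
in front of the neural networks (``suggested_dl``), and three literature
comparison pipelines (``pipeline_a``/``b``/``c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.ndimage import median_filter as _nd_median_filter
from scipy.signal import savgol_filter

from .core import REGIONS, Cohort, RegionSpec, select_region
from .dimreduce import PCAState, fit_pca, transform_pca

__all__ = [
    "snip_baseline",
    "l2_normalize",
    "snv_normalize",
    "median_filter",
    "smooth",
    "StageSpec",
    "PipelineSpec",
    "PRESETS",
    "get_preset",
    "apply_pipeline",
]

STAGE_KINDS = (
    "snip_baseline",
    "l2_normalize",
    "snv_normalize",
    "median_filter",
    "savgol_smooth",
    "gaussian_smooth",
    "pca",
)


def _lls(y: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(
    spectrum: np.ndarray, iterations: int = 80, *, lls: bool = False, decreasing: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract a smooth baseline by iterative peak clipping.

    Accepts a single spectrum or a (n_spectra, n_points) matrix; the clipping
    window half-width grows from 1 to ``iterations`` (set ``decreasing`` for
    the shrinking-window variant).  Points closer than the current half-width
    to either end are left unclipped so monotone spectrum ends are not eroded.
    Returns ``(corrected, baseline)``; the baseline never exceeds the input.

    Negative inputs (e.g. spectra already normalized elsewhere) are handled by
    shifting to non-negative before any LLS compression and shifting back.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y = np.atleast_2d(np.asarray(spectrum, dtype=float))
    if y.shape[1] == 0:
        raise ValueError("empty spectrum")
    offset = np.minimum(y.min(axis=1, keepdims=True), 0.0)
    v = _lls(y - offset) if lls else (y - offset)
    n = y.shape[1]
    windows = range(iterations, 0, -1) if decreasing else range(1, iterations + 1)
    for m in windows:
        if 2 * m >= n:
            continue
        # clip only where the full +-m window fits; clipping against a
        # self-anchored edge average would erode monotone spectrum ends
        inner = slice(m, n - m)
        v[:, inner] = np.minimum(v[:, inner], 0.5 * (v[:, : n - 2 * m] + v[:, 2 * m :]))
    baseline = (_lls_inv(v) if lls else v) + offset
    baseline = np.minimum(baseline, y)  # guard rounding in the decompression
    corrected = y - baseline
    if np.asarray(spectrum).ndim == 1:
        return corrected[0], baseline[0]
    return corrected, baseline


def l2_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm: x / sqrt(sum x_i^2)."""
    x = np.asarray(spectrum, dtype=float)
    norm = np.linalg.norm(x, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("cannot L2-normalize a zero-norm spectrum")
    return x / norm


def snv_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x - mean) / sd, population sd."""
    x = np.asarray(spectrum, dtype=float)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot SNV-normalize a constant (zero-variance) spectrum")
    return (x - x.mean(axis=-1, keepdims=True)) / sd


def median_filter(spectrum: np.ndarray, window: int = 5) -> np.ndarray:
    """Sliding-window median with mirror padding (edge sample not repeated)."""
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    if window % 2 == 0 or window < 3 or window > n:
        raise ValueError(f"window must be odd, >= 3 and <= spectrum length, got {window}")
    size = (1, window) if x.ndim == 2 else window
    return _nd_median_filter(x, size=size, mode="mirror")


def smooth(spectrum: np.ndarray, method: str, **params: Any) -> np.ndarray:
    """Savitzky-Golay (``savgol``) or Gaussian (``gaussian``) smoothing.

    Defaults: savgol window 11 / polyorder 3; gaussian sigma 2 samples,
    truncated at 4 sigma.  Mirror padding either way.
    """
    x = np.asarray(spectrum, dtype=float)
    if method == "savgol":
        window = int(params.get("window", 11))
        polyorder = int(params.get("polyorder", 3))
        if window % 2 == 0 or polyorder >= window:
            raise ValueError(f"savgol needs odd window > polyorder, got {window}/{polyorder}")
        return savgol_filter(x, window, polyorder, axis=-1, mode="mirror")
    if method == "gaussian":
        sigma = float(params.get("sigma", 2.0))
        if sigma <= 0:
            raise ValueError("gaussian sigma must be > 0")
        return gaussian_filter1d(x, sigma, axis=-1, mode="mirror", truncate=4.0)
    raise ValueError(f"unknown smoothing method {method!r}")


@dataclass(frozen=True)
class StageSpec:
    """One pipeline stage: a kind from ``STAGE_KINDS`` plus its parameters."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STAGE_KINDS:
            raise ValueError(f"unknown stage kind {self.kind!r}; expected one of {STAGE_KINDS}")
        p = self.params
        if self.kind == "snip_baseline" and p.get("iterations", 80) < 1:
            raise ValueError("snip_baseline iterations must be >= 1")
        if self.kind == "median_filter":
            w = p.get("window", 5)
            if w % 2 == 0 or w < 3:
                raise ValueError("median_filter window must be odd and >= 3")
        if self.kind == "savgol_smooth":
            w, po = p.get("window", 11), p.get("polyorder", 3)
            if w % 2 == 0 or w < 3 or po >= w:
                raise ValueError("savgol_smooth needs odd window >= 3 and polyorder < window")
        if self.kind == "gaussian_smooth" and p.get("sigma", 2.0) <= 0:
            raise ValueError("gaussian_smooth sigma must be > 0")
        if self.kind == "pca" and p.get("n_components", 30) < 1:
            raise ValueError("pca n_components must be >= 1")


@dataclass(frozen=True)
class PipelineSpec:
    """Named, ordered preprocessing recipe; the unit of ablation/comparison.

    Per-spectrum stages up to ``region_position`` run on the incoming grid;
    the region is then selected; remaining stages (at most a trailing ``pca``)
    run on the region-restricted data.  ``region_position=None`` places region
    selection after all per-spectrum stages, before any PCA.
    """

    name: str
    stages: tuple[StageSpec, ...]
    region: str = "full"
    region_position: int | None = None

    def __post_init__(self) -> None:
        pca_idx = [i for i, s in enumerate(self.stages) if s.kind == "pca"]
        if len(pca_idx) > 1:
            raise ValueError("at most one pca stage is allowed")
        if pca_idx and pca_idx[0] != len(self.stages) - 1:
            raise ValueError("the pca stage must come last")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.region_position is not None and not 0 <= self.region_position <= len(self.stages):
            raise ValueError("region_position out of bounds")

    @property
    def pca_components(self) -> int | None:
        for s in self.stages:
            if s.kind == "pca":
                return int(s.params.get("n_components", 30))
        return None

    def split_point(self) -> int:
        """Stage index at which region selection happens."""
        if self.region_position is not None:
            return self.region_position
        n_spectral = sum(1 for s in self.stages if s.kind != "pca")
        return n_spectral


def _preset(name: str, kinds: list[tuple[str, dict]], region: str = "low_plus_high") -> PipelineSpec:
    return PipelineSpec(name, tuple(StageSpec(k, p) for k, p in kinds), region=region)


#: Named pipelines.  ``suggested_ml`` is the main classical-model recipe
#: (baseline -> L2 -> median -> PCA(30)); ``suggested_dl`` keeps only the first
#: two stages for the neural networks; a/b/c are literature reference recipes.
PRESETS: dict[str, PipelineSpec] = {
    "suggested_ml": _preset(
        "suggested_ml",
        [
            ("snip_baseline", {"iterations": 80}),
            ("l2_normalize", {}),
            ("median_filter", {"window": 5}),
            ("pca", {"n_components": 30}),
        ],
    ),
    "suggested_dl": _preset(
        "suggested_dl",
        [("snip_baseline", {"iterations": 80}), ("l2_normalize", {})],
    ),
    "pipeline_a": _preset(
        "pipeline_a",
        [
            ("savgol_smooth", {"window": 11, "polyorder": 3}),
            ("snip_baseline", {"iterations": 80}),
            ("snv_normalize", {}),
            ("pca", {"n_components": 30}),
        ],
    ),
    "pipeline_b": _preset(
        "pipeline_b",
        [
            ("gaussian_smooth", {"sigma": 2.0}),
            ("snip_baseline", {"iterations": 80}),
            ("snv_normalize", {}),
            ("pca", {"n_components": 30}),
        ],
    ),
    "pipeline_c": _preset(
        "pipeline_c",
        [
            ("snip_baseline", {"iterations": 80}),
            ("snv_normalize", {}),
            ("savgol_smooth", {"window": 11, "polyorder": 3}),
        ],
    ),
}


def get_preset(name: str) -> PipelineSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown pipeline preset {name!r}; known: {sorted(PRESETS)}") from None


def pipeline_to_dict(spec: PipelineSpec) -> dict:
    """Plain-dict form of a pipeline, suitable for YAML/JSON."""
    return {
        "name": spec.name,
        "stages": [{"kind": s.kind, "params": dict(s.params)} for s in spec.stages],
        "region": spec.region,
        "region_position": spec.region_position,
    }


def pipeline_from_dict(d: dict) -> PipelineSpec:
    """Inverse of :func:`pipeline_to_dict`; validates on construction."""
    stages = tuple(StageSpec(s["kind"], dict(s.get("params", {}))) for s in d.get("stages", ()))
    return PipelineSpec(
        name=d.get("name", "custom"),
        stages=stages,
        region=d.get("region", "full"),
        region_position=d.get("region_position"),
    )


def _apply_stage(matrix: np.ndarray, stage: StageSpec) -> np.ndarray:
    p = stage.params
    if stage.kind == "snip_baseline":
        corrected, _ = snip_baseline(matrix, iterations=int(p.get("iterations", 80)))
        return corrected
    if stage.kind == "l2_normalize":
        return l2_normalize(matrix)
    if stage.kind == "snv_normalize":
        return snv_normalize(matrix)
    if stage.kind == "median_filter":
        return median_filter(matrix, window=int(p.get("window", 5)))
    if stage.kind == "savgol_smooth":
        return smooth(matrix, "savgol", **p)
    if stage.kind == "gaussian_smooth":
        return smooth(matrix, "gaussian", **p)
    raise ValueError(f"stage {stage.kind!r} is not a per-spectrum stage")


def apply_spectral_stages(cohort: Cohort, spec: PipelineSpec) -> Cohort:
    """Run the per-spectrum stages and region selection; skip any PCA.

    All per-spectrum stages are stateless, so this part of a pipeline is
    identical whether run on a training fold or on held-out data.
    """
    split = spec.split_point()
    matrix = cohort.matrix
    stages = [s for s in spec.stages if s.kind != "pca"]
    for stage in stages[:split]:
        matrix = _apply_stage(matrix, stage)
    out = cohort.with_matrix(matrix)
    out = select_region(out, spec.region)
    matrix = out.matrix
    for stage in stages[split:]:
        matrix = _apply_stage(matrix, stage)
    return out.with_matrix(matrix)


def apply_pipeline(
    cohort: Cohort, spec: PipelineSpec, fitted_state: PCAState | None = None
) -> tuple[Cohort | np.ndarray, PCAState | None]:
    """Run a full pipeline on a cohort.

    Returns ``(Cohort, None)`` for pipelines without PCA, or
    ``(score_matrix, PCAState)`` for pipelines ending in PCA.  When
    ``fitted_state`` is given the call is transform-only (held-out data);
    otherwise any PCA stage is fitted on this cohort.
    """
    processed = apply_spectral_stages(cohort, spec)
    k = spec.pca_components
    if k is None:
        if fitted_state is not None:
            raise ValueError(f"pipeline {spec.name!r} has no pca stage but a fitted state was given")
        return processed, None
    if fitted_state is not None:
        if fitted_state.n_features != len(processed.grid):
            raise ValueError(
                f"fitted PCA expects {fitted_state.n_features} features, "
                f"region {spec.region!r} yields {len(processed.grid)}"
            )
        return transform_pca(fitted_state, processed.matrix), fitted_state
    state = fit_pca(processed.matrix, k, source_region=spec.region)
    return transform_pca(state, processed.matrix), state
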