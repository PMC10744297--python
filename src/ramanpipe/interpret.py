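"""Grad-CAM saliency for 1-D convolutional spectral classifiers.

Gradient-weighted class activation mapping: for the feature maps ``A_k`` of
the last convolutional stage, the channel weights are the spatial means of
the gradient of the cancer-class *logit* with respect to ``A_k`` (the
pre-sigmoid score is used so a saturated sigmoid cannot zero the gradients).
The rectified weighted sum ``ReLU(sum_k alpha_k A_k)`` is linearly
interpolated back to the input wavenumber axis and min-max normalized, giving
a per-wavenumber importance profile that can be averaged over spectra and
thresholded into discriminative wavenumber bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core import SpectralGrid

__all__ = ["SaliencyMap", "Band", "BandSet", "gradcam_map", "gradcam_maps", "aggregate_saliency"]


@dataclass(frozen=True)
class SaliencyMap:
    """Per-wavenumber importance in [0, 1] on a (region-selected) grid."""

    grid: SpectralGrid
    importance: np.ndarray
    source: str = ""
    target_layer: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        imp = np.asarray(self.importance, dtype=float)
        object.__setattr__(self, "importance", imp)
        if imp.shape != (len(self.grid),):
            raise ValueError("importance length must match the grid")
        if not self.degenerate and (imp.min() < -1e-12 or abs(imp.max() - 1.0) > 1e-9):
            raise ValueError("non-degenerate saliency must be min-max normalized to [0, 1]")


@dataclass(frozen=True)
class Band:
    lo: float
    hi: float
    mean_importance: float


@dataclass(frozen=True)
class BandSet:
    bands: tuple[Band, ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.bands)


def _target_layer_index(model: nn.Sequential) -> int:
    """Index of the last conv stage's post-activation feature maps.

    For a plain conv stack this is the ReLU following the final Conv1D (a
    residual block's output is already rectified).  Using the rectified maps
    matters: pre-activation maps can encode class evidence with a negative
    sign, which the CAM's closing ReLU would silently discard.
    """
    idx = [
        i
        for i, layer in enumerate(model.layers)
        if isinstance(layer, (nn.Conv1D, nn.ResidualBlock1D))
    ]
    if not idx:
        raise ValueError("Grad-CAM needs a model with at least one convolutional layer")
    i = idx[-1]
    if (
        isinstance(model.layers[i], nn.Conv1D)
        and i + 1 < len(model.layers)
        and isinstance(model.layers[i + 1], nn.ReLU)
    ):
        return i + 1
    return i


def _raw_cam(model: nn.Sequential, X: np.ndarray) -> np.ndarray:
    """Unnormalized CAM per spectrum, upsampled to input length. X: (n, length)."""
    x = np.asarray(X, dtype=float)[:, None, :]
    ti = _target_layer_index(model)
    model.forward(x, training=False, record=True)
    A = model.layer_outputs[ti]  # (n, K, L')
    n = x.shape[0]
    dA = model.backward(np.ones((n, 1)), stop_after=ti)
    alpha = dA.mean(axis=2, keepdims=True)  # (n, K, 1)
    cam = np.maximum((alpha * A).sum(axis=1), 0.0)  # (n, L')
    L_in, L_map = x.shape[2], cam.shape[1]
    if L_map == L_in:
        return cam
    pos_map = np.linspace(0, L_in - 1, L_map)
    return np.vstack([np.interp(np.arange(L_in), pos_map, c) for c in cam])


def gradcam_map(
    model: nn.Sequential, spectrum: np.ndarray, grid: SpectralGrid, source: str = ""
) -> SaliencyMap:
    """Saliency of one preprocessed spectrum for the cancerous-class logit.

    All-zero maps (zero gradients, e.g. a dead final layer) are returned
    unnormalized with ``degenerate=True``.
    """
    cam = _raw_cam(model, np.asarray(spectrum, dtype=float)[None, :])[0]
    peak = cam.max()
    if peak <= 0:
        return SaliencyMap(grid, cam, source=source, target_layer="last_conv", degenerate=True)
    lo = cam.min()
    return SaliencyMap(grid, (cam - lo) / (peak - lo), source=source, target_layer="last_conv")


def gradcam_maps(model: nn.Sequential, X: np.ndarray, grid: SpectralGrid) -> list[SaliencyMap]:
    """Batch variant of :func:`gradcam_map`."""
    cams = _raw_cam(model, X)
    maps = []
    for i, cam in enumerate(cams):
        peak, lo = cam.max(), cam.min()
        if peak <= 0:
            maps.append(SaliencyMap(grid, cam, source=f"row{i}", target_layer="last_conv",
                                    degenerate=True))
        else:
            maps.append(SaliencyMap(grid, (cam - lo) / (peak - lo), source=f"row{i}",
                                    target_layer="last_conv"))
    return maps


def aggregate_saliency(maps: list[SaliencyMap], threshold: float = 0.5) -> BandSet:
    """Mean saliency over spectra, thresholded into contiguous wavenumber bands.

    The pointwise mean map is re-normalized to unit maximum; maximal runs of
    grid points at or above ``threshold`` (as a fraction of that maximum)
    become bands, reported with their mean importance, sorted by position.
    """
    if not maps:
        raise ValueError("aggregate_saliency needs at least one map")
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid != grid:
            raise ValueError("all saliency maps must share a grid")
    mean = np.mean([m.importance for m in maps], axis=0)
    peak = mean.max()
    if peak > 0:
        mean = mean / peak
    above = mean >= threshold
    bands: list[Band] = []
    i, n = 0, len(mean)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            bands.append(
                Band(
                    lo=float(grid.shifts[i]),
                    hi=float(grid.shifts[j]),
                    mean_importance=float(mean[i : j + 1].mean()),
                )
            )
            i = j + 1
        else:
            i += 1
    return BandSet(bands=tuple(bands), threshold=threshold)
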