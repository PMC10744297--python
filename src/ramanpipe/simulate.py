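"""Synthetic patient-structured Raman cohort generator.

Real tissue spectra behind this kind of study are rarely public, so every
downstream stage here is exercised on simulated cohorts with known ground
truth.  A spectrum is built as

    clean(nu) * gain + baseline_amplitude * b_jitter * B(nu) + noise + spikes

where ``clean`` is a sum of Lorentzian bands whose amplitudes differ between
the healthy and cancerous class, ``B`` is a smooth autofluorescence-like
background, ``gain`` and ``b_jitter`` are per-spectrum log-normal factors,
noise is additive Gaussian, and spikes are sparse cosmic-ray-like impulses.
Patient-level log-normal multipliers on the protein / lipid / collagen band
groups give every patient a biochemical signature, which is what makes
leave-one-patient-out validation meaningfully harder than spectrum-level
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import CANCEROUS, HEALTHY, Cohort, SpectralGrid, SpectrumRecord, build_default_grid

__all__ = [
    "PeakSpec",
    "SimulatorConfig",
    "default_peak_library",
    "synth_clean_spectrum",
    "generate_cohort",
]

GROUPS = ("protein", "lipid", "collagen", "other")


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: Lorentzian center/width and per-class amplitudes."""

    center: float
    fwhm: float
    amp_healthy: float
    amp_cancer: float
    group: str = "other"

    def __post_init__(self) -> None:
        if not 0 < self.fwhm <= 200:
            raise ValueError(f"fwhm must be in (0, 200], got {self.fwhm}")
        if self.amp_healthy < 0 or self.amp_cancer < 0:
            raise ValueError("band amplitudes must be non-negative")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    def amp(self, label: int) -> float:
        return self.amp_cancer if label == CANCEROUS else self.amp_healthy


def default_peak_library() -> list[PeakSpec]:
    """Band library for a colorectal-tissue-like cohort.

    Class contrast encodes protein overexpression in cancerous tissue and a
    higher lipid-to-protein ratio in healthy tissue: protein bands carry a
    cancer/healthy amplitude ratio of 1.3, lipid bands 0.7, collagen 1.2.
    Fingerprint bands default to 15 cm^-1 FWHM, CH-stretch bands to 40 cm^-1.
    """

    def band(center, group, ratio, amp=1.0, fwhm=None):
        fwhm = fwhm if fwhm is not None else (40.0 if center >= 2800 else 15.0)
        return PeakSpec(center, fwhm, amp_healthy=amp, amp_cancer=amp * ratio, group=group)

    protein, lipid, collagen = 1.3, 0.7, 1.2
    return [
        band(866.0, "collagen", collagen),
        band(1005.0, "protein", protein),        # phenylalanine
        band(1250.0, "collagen", collagen, 0.8),  # amide III
        band(1330.0, "protein", protein, 0.9),
        band(1342.0, "protein", protein),
        band(1437.0, "lipid", lipid),             # CH2 deformation
        band(1450.0, "lipid", lipid, 0.9),
        band(1658.0, "protein", protein, 0.9),    # amide I
        band(1671.0, "protein", protein),
        band(1748.0, "lipid", lipid),             # C=O ester
        band(2852.0, "lipid", lipid, 1.5),        # CH2 symmetric stretch
        band(2890.0, "lipid", lipid, 1.2),
        band(2935.0, "protein", protein, 1.5),    # CH3 stretch
        band(2974.0, "protein", protein),
    ]


@dataclass
class SimulatorConfig:
    """Knobs of the cohort simulator; defaults emulate a 22-patient study.

    22 patients contribute ``spectra_per_patient_per_class`` spectra per class
    (default 10), plus one extra healthy/cancerous pair assigned to the first
    patient, giving the canonical 221 + 221 = 442 spectra.
    """

    n_patients: int = 22
    spectra_per_patient_per_class: int = 10
    extra_pairs_first_patient: int = 1
    peaks: list[PeakSpec] = field(default_factory=default_peak_library)
    baseline_amplitude: float = 2.0
    baseline_decay: float = 1200.0      # cm^-1 e-folding of the exponential term
    baseline_hump_center: float = 1400.0
    baseline_hump_sigma: float = 600.0
    baseline_jitter_sd: float = 0.3     # per-spectrum log-normal sd on the background
    noise_sd: float = 0.03
    gain_sd: float = 0.3                # per-spectrum log-normal sd on the Raman signal
    patient_effect_sd: float = 0.15     # per-patient log-normal sd on band-group amplitudes
    spike_prob: float = 0.002           # per-channel impulse probability
    spike_amp: float = 5.0
    seed: int = 0

    def validate(self, grid: SpectralGrid) -> None:
        bad = [
            name
            for name in (
                "baseline_amplitude",
                "baseline_jitter_sd",
                "noise_sd",
                "gain_sd",
                "patient_effect_sd",
                "spike_amp",
            )
            if getattr(self, name) < 0
        ]
        if not 0 <= self.spike_prob <= 1:
            bad.append("spike_prob")
        if self.n_patients < 1:
            bad.append("n_patients")
        if self.spectra_per_patient_per_class < 1:
            bad.append("spectra_per_patient_per_class")
        if bad:
            raise ValueError(f"invalid simulator config field(s): {bad}")
        lo, hi = grid.shifts[0], grid.shifts[-1]
        off = [p.center for p in self.peaks if not lo <= p.center <= hi]
        if off:
            raise ValueError(f"peak centers outside the grid span [{lo}, {hi}]: {off}")


def lorentzian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian lineshape (gamma/2)^2 / ((nu-c)^2 + (gamma/2)^2)."""
    hw = fwhm / 2.0
    return hw**2 / ((nu - center) ** 2 + hw**2)


def synth_clean_spectrum(
    grid: SpectralGrid,
    peaks: Sequence[PeakSpec],
    label: int,
    patient_multipliers: dict[str, float] | None = None,
) -> np.ndarray:
    """Noise- and baseline-free class template: a sum of Lorentzian bands.

    ``patient_multipliers`` maps band-group name to a scalar factor; missing
    groups default to 1.
    """
    mult = patient_multipliers or {}
    out = np.zeros(len(grid))
    for p in peaks:
        out += p.amp(label) * mult.get(p.group, 1.0) * lorentzian(grid.shifts, p.center, p.fwhm)
    return out


def autofluorescence_shape(grid: SpectralGrid, config: SimulatorConfig) -> np.ndarray:
    """Smooth broad background, normalized to unit maximum.

    A decaying exponential in wavenumber plus a broad Gaussian hump — curved
    enough to be a realistic confounder, smooth enough that iterative peak
    clipping can remove it.
    """
    nu = grid.shifts
    shape = np.exp(-(nu - nu[0]) / config.baseline_decay) + np.exp(
        -0.5 * ((nu - config.baseline_hump_center) / config.baseline_hump_sigma) ** 2
    )
    return shape / shape.max()


def generate_cohort(config: SimulatorConfig | None = None, grid: SpectralGrid | None = None) -> Cohort:
    """Simulate a patient-structured cohort; deterministic given the seed.

    Draw order is fixed (per-patient group multipliers, then per spectrum:
    gain, baseline jitter, noise, spikes) so that a seed pins the cohort
    bitwise across runs.  Labels are balanced within every patient.
    Intensities are clipped at zero, as photon counts are.
    """
    config = config if config is not None else SimulatorConfig()
    grid = grid if grid is not None else build_default_grid()
    config.validate(grid)
    rng = np.random.default_rng(config.seed)

    baseline = autofluorescence_shape(grid, config)
    patient_mults = [
        {g: float(np.exp(rng.normal(0.0, config.patient_effect_sd))) for g in GROUPS[:3]}
        for _ in range(config.n_patients)
    ]

    records: list[SpectrumRecord] = []
    for pi in range(config.n_patients):
        pid = f"P{pi + 1:02d}"
        n_per_class = config.spectra_per_patient_per_class + (
            config.extra_pairs_first_patient if pi == 0 else 0
        )
        templates = {
            lab: synth_clean_spectrum(grid, config.peaks, lab, patient_mults[pi])
            for lab in (HEALTHY, CANCEROUS)
        }
        for lab in (HEALTHY, CANCEROUS):
            tag = "H" if lab == HEALTHY else "C"
            for si in range(n_per_class):
                gain = np.exp(rng.normal(0.0, config.gain_sd))
                b_jitter = np.exp(rng.normal(0.0, config.baseline_jitter_sd))
                y = templates[lab] * gain + config.baseline_amplitude * b_jitter * baseline
                y = y + rng.normal(0.0, config.noise_sd, size=len(grid))
                spikes = rng.random(len(grid)) < config.spike_prob
                y = y + spikes * config.spike_amp * rng.random(len(grid))
                records.append(
                    SpectrumRecord(
                        spectrum_id=f"{pid}_{tag}{si:02d}",
                        patient_id=pid,
                        label=lab,
                        intensities=np.clip(y, 0.0, None),
                    )
                )
    provenance = {
        "generator": "ramanpipe.simulate.generate_cohort",
        "seed": config.seed,
        "n_patients": config.n_patients,
        "noise_sd": config.noise_sd,
        "baseline_amplitude": config.baseline_amplitude,
    }
    return Cohort(grid=grid, records=records, provenance=provenance)
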