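"""Spectral axis, region selection, and cohort file I/O.

The central containers are :class:`SpectralGrid` (the shared Raman-shift axis,
in cm^-1), :class:`SpectrumRecord` (one spectrum plus patient/label metadata)
and :class:`Cohort` (the unit that every pipeline consumes).  Cohorts are
persisted as a plain CSV intensity matrix plus a JSON manifest so that no
proprietary spectrometer format is ever needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "RegionSpec",
    "SpectrumRecord",
    "Cohort",
    "REGIONS",
    "build_default_grid",
    "select_region",
    "read_cohort",
    "write_cohort",
]

#: Absolute tolerance (cm^-1) when comparing grid points to region endpoints,
#: so that on-grid endpoints like 700 or 2800 survive floating-point assembly.
ENDPOINT_TOL = 1e-6

HEALTHY, CANCEROUS = 0, 1
LABEL_NAMES = {HEALTHY: "healthy", CANCEROUS: "cancerous"}


@dataclass(frozen=True)
class SpectralGrid:
    """Ordered Raman-shift axis (cm^-1) shared by a cohort's spectra."""

    shifts: np.ndarray

    def __post_init__(self) -> None:
        shifts = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "shifts", shifts)
        if shifts.ndim != 1 or shifts.size < 2:
            raise ValueError("grid needs at least 2 one-dimensional shift values")
        if not np.all(np.diff(shifts) > 0):
            raise ValueError("Raman-shift axis must be strictly increasing")
        if shifts[0] < 0 or shifts[-1] >= 10000:
            raise ValueError("Raman shifts must lie within [0, 10000) cm^-1")

    def __len__(self) -> int:
        return int(self.shifts.size)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SpectralGrid) and np.array_equal(self.shifts, other.shifts)

    def mask_for(self, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
        """Boolean mask of grid points inside any closed [lo, hi] interval."""
        mask = np.zeros(len(self), dtype=bool)
        for lo, hi in intervals:
            mask |= (self.shifts >= lo - ENDPOINT_TOL) & (self.shifts <= hi + ENDPOINT_TOL)
        return mask


@dataclass(frozen=True)
class RegionSpec:
    """A named union of closed wavenumber intervals used for band selection."""

    name: str
    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for lo, hi in ivs:
            if lo >= hi:
                raise ValueError(f"interval [{lo}, {hi}] must have lo < hi")
        for (_, hi), (lo2, _) in zip(ivs, ivs[1:]):
            if lo2 <= hi:
                raise ValueError("region intervals must be non-overlapping and sorted")


#: The study's region alternations: the fingerprint ("low") region, the
#: CH-stretch ("high") region, their union, and the full acquired axis.
REGIONS: dict[str, RegionSpec] = {
    "low": RegionSpec("low", ((700.0, 1800.0),)),
    "high": RegionSpec("high", ((2800.0, 3100.0),)),
    "low_plus_high": RegionSpec("low_plus_high", ((700.0, 1800.0), (2800.0, 3100.0))),
    "full": RegionSpec("full", ((0.0, 9999.0),)),
}


@dataclass
class SpectrumRecord:
    """One spectrum: id, patient, binary label and an intensity vector.

    Labels are fixed as 0 = healthy, 1 = cancerous.  Raw intensities are
    non-negative counts; preprocessed intensities may be negative (baseline
    subtraction) so no sign constraint is enforced here.
    """

    spectrum_id: str
    patient_id: str
    label: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.label not in (HEALTHY, CANCEROUS):
            raise ValueError(f"label must be 0 (healthy) or 1 (cancerous), got {self.label!r}")


@dataclass
class Cohort:
    """A spectra matrix with per-spectrum metadata; the unit of all pipelines."""

    grid: SpectralGrid
    records: list[SpectrumRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.grid)
        seen: set[str] = set()
        for rec in self.records:
            if rec.intensities.size != n:
                raise ValueError(
                    f"spectrum {rec.spectrum_id!r} has {rec.intensities.size} points, grid has {n}"
                )
            if rec.spectrum_id in seen:
                raise ValueError(f"duplicate spectrum_id {rec.spectrum_id!r}")
            seen.add(rec.spectrum_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def matrix(self) -> np.ndarray:
        """Intensity matrix, shape (n_spectra, n_grid_points)."""
        if not self.records:
            return np.empty((0, len(self.grid)))
        return np.vstack([r.intensities for r in self.records])

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def spectrum_ids(self) -> list[str]:
        return [r.spectrum_id for r in self.records]

    def with_matrix(self, matrix: np.ndarray, grid: SpectralGrid | None = None) -> "Cohort":
        """Copy of the cohort with replaced intensities (and optionally grid)."""
        grid = grid if grid is not None else self.grid
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(self.records), len(grid)):
            raise ValueError(f"matrix shape {matrix.shape} does not match cohort/grid")
        records = [replace(r, intensities=matrix[i].copy()) for i, r in enumerate(self.records)]
        return Cohort(grid=grid, records=records, provenance=dict(self.provenance))


def build_default_grid() -> SpectralGrid:
    """Reference acquisition axis over 500-3200 cm^-1.

    Two uniform segments: a fingerprint-side segment starting at 500 cm^-1
    with spacing 1100/1210 cm^-1 (2530 points, ending just below 2800) and a
    denser high-wavenumber segment from 2800 cm^-1 with spacing 300/476 cm^-1
    (635 points).  The denser high side is consistent with a constant
    detector-pixel pitch in wavelength under 785 nm excitation.  With this
    axis the low / high / low+high selections contain 1211 / 477 / 1688
    points — the dimensionalities the downstream classifiers expect.
    """
    seg_a = 500.0 + np.arange(2530) * (1100.0 / 1210.0)
    seg_b = 2800.0 + np.arange(635) * (300.0 / 476.0)
    return SpectralGrid(np.concatenate([seg_a, seg_b]))


def select_region(cohort: Cohort, region: RegionSpec | str) -> Cohort:
    """Restrict a cohort to the grid columns inside a region's intervals.

    Interval bounds are closed, compared with a small absolute tolerance so
    that on-grid endpoints are kept.  Column order and record metadata are
    preserved.
    """
    if isinstance(region, str):
        region = REGIONS[region]
    mask = cohort.grid.mask_for(region.intervals)
    if not mask.any():
        raise ValueError(f"region {region.name!r} ({region.intervals}) selects no grid points")
    new_grid = SpectralGrid(cohort.grid.shifts[mask])
    records = [replace(r, intensities=r.intensities[mask]) for r in cohort.records]
    return Cohort(grid=new_grid, records=records, provenance=dict(cohort.provenance))


def write_cohort(cohort: Cohort, spectra_path: str | Path, manifest_path: str | Path) -> None:
    """Persist a cohort as a CSV intensity matrix plus a JSON manifest.

    The CSV header row holds the Raman shifts; the first column holds
    spectrum ids.  Values are written with 17 significant digits so a
    round-trip through :func:`read_cohort` preserves them to better than
    1e-12 relative.
    """
    spectra_path, manifest_path = Path(spectra_path), Path(manifest_path)
    df = pd.DataFrame(
        cohort.matrix,
        index=pd.Index(cohort.spectrum_ids, name="spectrum_id"),
        columns=[f"{s:.17g}" for s in cohort.grid.shifts],
    )
    df.to_csv(spectra_path, float_format="%.17g")
    manifest = {
        "provenance": cohort.provenance,
        "spectra": [
            {"spectrum_id": r.spectrum_id, "patient_id": r.patient_id, "label": int(r.label)}
            for r in cohort.records
        ],
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))


def read_cohort(spectra_path: str | Path, manifest_path: str | Path) -> Cohort:
    """Load and validate a cohort written by :func:`write_cohort`.

    Every spectrum row must have a manifest entry and vice versa; the header
    grid must be strictly increasing; labels must be 0/1.
    """
    spectra_path, manifest_path = Path(spectra_path), Path(manifest_path)
    df = pd.read_csv(spectra_path, index_col=0, sep=None, engine="python")
    shifts = np.array([float(c) for c in df.columns])
    if shifts.size >= 2 and not np.all(np.diff(shifts) > 0):
        raise ValueError("non-monotone grid: spectra header shifts must be strictly increasing")
    payload = json.loads(Path(manifest_path).read_text())
    entries = payload["spectra"] if isinstance(payload, dict) else payload
    meta: dict[str, dict] = {}
    for e in entries:
        sid = e["spectrum_id"]
        if sid in meta:
            raise ValueError(f"duplicate spectrum_id {sid!r} in manifest")
        if e["label"] not in (HEALTHY, CANCEROUS):
            raise ValueError(f"unknown label {e['label']!r} for spectrum {sid!r}")
        meta[sid] = e
    csv_ids = [str(i) for i in df.index]
    missing = [sid for sid in csv_ids if sid not in meta]
    if missing:
        raise ValueError(f"manifest missing spectrum_id(s): {missing}")
    extra = [sid for sid in meta if sid not in set(csv_ids)]
    if extra:
        raise ValueError(f"manifest has entries absent from the spectra matrix: {extra}")
    if len(set(csv_ids)) != len(csv_ids):
        raise ValueError("duplicate spectrum_id in spectra matrix")
    records = [
        SpectrumRecord(
            spectrum_id=sid,
            patient_id=meta[sid]["patient_id"],
            label=int(meta[sid]["label"]),
            intensities=df.loc[sid].to_numpy(dtype=float),
        )
        for sid in csv_ids
    ]
    provenance = payload.get("provenance", {}) if isinstance(payload, dict) else {}
    if not records:
        # degenerate but valid: empty cohort keeps the header grid
        return Cohort(grid=SpectralGrid(shifts), records=[], provenance=provenance)
    return Cohort(grid=SpectralGrid(shifts), records=records, provenance=provenance)
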