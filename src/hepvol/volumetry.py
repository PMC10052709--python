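"""Volume estimators: slice summation and slice-decimated extrapolation.

Volumetry here is Cavalieri-style slice summation: the full hepatic volume
is

    V_full = sum_i A_i * t

with ``A_i`` the traced liver area on slice ``i`` (cm^2) and ``t`` the
slice thickness (cm).  When only every k-th slice is traced (slice
interval = k * t), the volume is extrapolated from the subset:

    V_dec = (sum_{i in subset} A_i * t) * N / n_used

where ``N`` is the total number of liver-bearing slices and ``n_used`` the
number of slices actually used.  For a decimation factor k there are k
possible phase offsets (which slice is traced first), each giving one
estimate; the phase subsets partition the N slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .series import MaskVolume, SliceSeries


def _fmt_mm(value_cm: float) -> str:
    """Format a length in cm as its mm magnitude, shortest form (0.25 -> '2.5')."""
    return f"{value_cm * 10:g}"


@dataclass(frozen=True)
class DecimationScheme:
    """One "slice thickness - slice interval" sampling scheme.

    ``k = interval / thickness`` is the decimation factor: every k-th
    slice is used.  ``k == 1`` denotes the full (no gap) scheme, labelled
    e.g. ``"2.5-full"``; otherwise the label is thickness-interval in mm,
    e.g. ``"2.5-7.5"``.
    """

    thickness_cm: float
    interval_cm: float

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0 or self.interval_cm <= 0:
            raise DataError("thickness and interval must be > 0")
        ratio = self.interval_cm / self.thickness_cm
        k = round(ratio)
        if k < 1 or abs(ratio - k) > 1e-9 * max(1.0, abs(ratio)):
            raise DataError(
                f"interval ({self.interval_cm} cm) must be an exact integer multiple "
                f"of thickness ({self.thickness_cm} cm)"
            )

    @property
    def k(self) -> int:
        """Decimation factor (number of phase offsets)."""
        return round(self.interval_cm / self.thickness_cm)

    @property
    def is_full(self) -> bool:
        return self.k == 1

    @property
    def group_label(self) -> str:
        if self.is_full:
            return f"{_fmt_mm(self.thickness_cm)}-full"
        return f"{_fmt_mm(self.thickness_cm)}-{_fmt_mm(self.interval_cm)}"


@dataclass(frozen=True)
class DecimatedMeasurement:
    """One extrapolated volume estimate from one phase-offset slice subset."""

    subject_id: str
    observer_id: str
    group_label: str
    thickness_cm: float
    interval_cm: float
    phase: int
    n_used: int
    n_total: int
    volume_cm3: float


def full_volume(series: SliceSeries) -> float:
    """Full hepatic volume: sum of (slice area x slice thickness), cm^3."""
    return float(series.thickness_cm * np.sum(series.areas_cm2))


def phase_subsets(n_slices: int, k: int) -> list[np.ndarray]:
    """The k phase-offset index subsets {p, p+k, p+2k, ...} for 0 <= p < k.

    The subsets are pairwise disjoint and their union is all ``n_slices``
    indices; subset p has ceil((n_slices - p) / k) members.
    """
    if k < 1:
        raise DataError(f"decimation factor k must be >= 1, got {k}")
    if n_slices < 1:
        raise DataError("n_slices must be >= 1")
    return [np.arange(p, n_slices, k) for p in range(k)]


def enumerate_phases(series: SliceSeries, scheme: DecimationScheme) -> list[np.ndarray]:
    """Phase subsets of ``series`` under ``scheme`` (thicknesses must match)."""
    if abs(scheme.thickness_cm - series.thickness_cm) > 1e-9:
        raise DataError(
            f"scheme thickness {scheme.thickness_cm} cm does not match "
            f"series thickness {series.thickness_cm} cm"
        )
    return phase_subsets(series.n_slices, scheme.k)


def decimated_volume(series: SliceSeries, subset: np.ndarray) -> float:
    """Extrapolated volume from a slice subset.

    Implements subset slice summation scaled by N / n_used.  With the full
    subset this reduces exactly to :func:`full_volume`; on a constant-area
    profile it is exact for every subset.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise DataError("slice subset must be non-empty")
    if np.unique(subset).size != subset.size:
        raise DataError("slice subset indices must be unique")
    if subset.min() < 0 or subset.max() >= series.n_slices:
        raise DataError("slice subset indices out of range")
    partial = series.thickness_cm * np.sum(series.areas_cm2[subset])
    return float(partial * series.n_slices / subset.size)


def measure_all(series: SliceSeries, scheme: DecimationScheme) -> list[DecimatedMeasurement]:
    """One :class:`DecimatedMeasurement` per phase offset, in phase order."""
    out = []
    for phase, subset in enumerate(enumerate_phases(series, scheme)):
        out.append(
            DecimatedMeasurement(
                subject_id=series.subject_id,
                observer_id=series.observer_id,
                group_label=scheme.group_label,
                thickness_cm=scheme.thickness_cm,
                interval_cm=scheme.interval_cm,
                phase=phase,
                n_used=int(subset.size),
                n_total=series.n_slices,
                volume_cm3=decimated_volume(series, subset),
            )
        )
    return out


def mask_to_series(
    mask: MaskVolume, observer_id: str = "mask", subject_id: str | None = None
) -> SliceSeries:
    """Per-slice areas from a binary mask volume.

    Slice area = foreground pixel count x row pitch x column pitch,
    converted mm^2 -> cm^2; leading/trailing all-background slices are
    trimmed.  An interior all-background slice (a gap in the liver) is kept
    as a zero area with a warning, since trimming must not fabricate
    contiguity.
    """
    counts = mask.voxels.sum(axis=(1, 2))
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 0:  # unreachable given MaskVolume validation
        raise DataError("mask contains no foreground voxels")
    counts = counts[nonzero[0] : nonzero[-1] + 1]
    if np.any(counts == 0):
        warnings.warn(
            f"mask {mask.subject_id!r} has interior all-background slices; "
            "retained as zero areas",
            stacklevel=2,
        )
    pixel_area_cm2 = mask.spacing_mm[1] * mask.spacing_mm[2] / 100.0
    return SliceSeries(
        subject_id=mask.subject_id if subject_id is None else subject_id,
        observer_id=observer_id,
        thickness_cm=mask.spacing_mm[0] / 10.0,
        areas_cm2=counts * pixel_area_cm2,
    )
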