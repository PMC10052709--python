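"""Core data containers shared across the package.

A :class:`SliceSeries` is the unit of all volumetry: the ordered liver
cross-sectional areas (cm^2) traced on consecutive transverse CT slices of
fixed thickness, covering exactly the liver-bearing slices (first and last
areas strictly positive, no leading/trailing zero padding).  A
:class:`MaskVolume` is the voxel embodiment of the same information: a 3-D
binary segmentation mask with its voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: column order of the long-format cohort CSV
SERIES_CSV_COLUMNS = ["subject", "observer", "slice_index", "area_cm2", "thickness_cm"]


@dataclass(frozen=True)
class SliceSeries:
    """Per-slice liver cross-sectional areas at a fixed slice thickness.

    Parameters
    ----------
    subject_id, observer_id : str
        Identifiers of the scanned subject and the tracing observer.
    thickness_cm : float
        Axial slice thickness in cm (e.g. 0.25 for a 2.5 mm acquisition).
    areas_cm2 : array-like of float
        Liver area on each consecutive liver-bearing slice, cranial to
        caudal, in cm^2.  First and last entries must be > 0; interior
        zeros are tolerated (they would represent a traced gap) but the
        series must not be padded with zeros at either end.
    """

    subject_id: str
    observer_id: str
    thickness_cm: float
    areas_cm2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas_cm2, dtype=float)
        areas.setflags(write=False)
        object.__setattr__(self, "areas_cm2", areas)
        if not np.isfinite(self.thickness_cm) or self.thickness_cm <= 0:
            raise DataError(f"thickness_cm must be > 0, got {self.thickness_cm}")
        if areas.ndim != 1 or areas.size < 1:
            raise DataError("areas_cm2 must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(areas)) or np.any(areas < 0):
            raise DataError("areas_cm2 must be finite and non-negative")
        if areas[0] <= 0 or areas[-1] <= 0:
            raise DataError(
                "first and last slice areas must be > 0 "
                "(series covers exactly the liver-bearing slices)"
            )

    @property
    def n_slices(self) -> int:
        """N, the total number of liver-bearing slices."""
        return int(self.areas_cm2.size)

    def with_areas(self, areas_cm2: np.ndarray, observer_id: str | None = None) -> "SliceSeries":
        """Copy of this series with replaced areas (and optionally observer)."""
        return SliceSeries(
            subject_id=self.subject_id,
            observer_id=self.observer_id if observer_id is None else observer_id,
            thickness_cm=self.thickness_cm,
            areas_cm2=areas_cm2,
        )


@dataclass(frozen=True)
class MaskVolume:
    """Binary liver segmentation mask with voxel spacing.

    ``voxels`` is indexed (slice, row, column); ``spacing_mm`` gives
    (slice thickness, row pitch, column pitch) in mm.
    """

    voxels: np.ndarray = field(repr=False)
    spacing_mm: tuple[float, float, float]
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=bool)
        voxels.setflags(write=False)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if voxels.ndim != 3:
            raise DataError("voxels must be a 3-D (slice, row, column) array")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise DataError(f"spacing_mm components must be > 0, got {self.spacing_mm}")
        if not voxels.any():
            raise DataError("mask contains no foreground voxels")


def write_series_csv(series_list: list[SliceSeries], path: str | Path) -> pd.DataFrame:
    """Write series in long format (one row per subject/observer/slice)."""
    rows = []
    for s in series_list:
        for i, a in enumerate(s.areas_cm2):
            rows.append((s.subject_id, s.observer_id, i, a, s.thickness_cm))
    df = pd.DataFrame(rows, columns=SERIES_CSV_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_series_csv(path: str | Path) -> list[SliceSeries]:
    """Read a long-format cohort CSV back into SliceSeries objects.

    Series are returned sorted by (subject, observer); slice order follows
    ``slice_index``.
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV {path} missing columns: {missing}")
    if len(df) == 0:
        raise DataError(f"cohort CSV {path} is empty")
    out: list[SliceSeries] = []
    for (subj, obs), grp in df.groupby(["subject", "observer"], sort=True):
        grp = grp.sort_values("slice_index")
        thick = grp["thickness_cm"].unique()
        if thick.size != 1:
            raise DataError(f"inconsistent thickness for subject={subj} observer={obs}")
        idx = grp["slice_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise DataError(
                f"slice_index for subject={subj} observer={obs} must be 0..N-1 without gaps"
            )
        out.append(
            SliceSeries(
                subject_id=str(subj),
                observer_id=str(obs),
                thickness_cm=float(thick[0]),
                areas_cm2=grp["area_cm2"].to_numpy(dtype=float),
            )
        )
    return out
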