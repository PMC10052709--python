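"""Interobserver agreement statistics on full-volume measurements.

Per subject, the spread of the observers' full hepatic volumes is
summarised by the coefficient of variation (CV = SD / mean x 100, sample
SD), the greatest percent difference ((max - min) / mean of all observers
x 100), and symmetric pairwise percent differences
(|a - b| / ((a + b)/2) x 100).  Cohort-level summaries are the mean +/-
sample SD of each statistic across subjects, plus the cohort mean +/- SD
of the volumes themselves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, IncompleteCohortError
from .series import SliceSeries
from .volumetry import full_volume


def _check_values(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise DataError("values must be finite")
    if v.mean() <= 0:
        raise DataError("mean of values must be > 0")
    return v


def cv(values) -> float:
    """Coefficient of variation, percent: sample SD (n-1) / mean x 100."""
    v = _check_values(values)
    return float(v.std(ddof=1) / v.mean() * 100.0)


def greatest_percent_difference(values) -> float:
    """(max - min) / mean of all values x 100.

    With exactly two values this coincides with
    :func:`pairwise_percent_difference`.
    """
    v = _check_values(values)
    return float((v.max() - v.min()) / v.mean() * 100.0)


def pairwise_percent_difference(a: float, b: float) -> float:
    """|a - b| / pair mean x 100 (symmetric in a, b)."""
    if a <= 0 or b <= 0:
        raise DataError("volumes must be > 0")
    return float(abs(a - b) / ((a + b) / 2.0) * 100.0)


@dataclass(frozen=True)
class InterobserverSummary:
    """Per-subject agreement of the observers' full volumes."""

    subject_id: str
    observer_ids: tuple[str, ...]
    volumes_cm3: tuple[float, ...]
    cv_pct: float
    greatest_pct_diff: float
    #: {(obs_i, obs_j): percent difference} for i < j
    pairwise_pct_diff: dict[tuple[str, str], float]


def summarize_subject(
    subject_id: str, volumes_by_observer: dict[str, float]
) -> InterobserverSummary:
    """Agreement statistics for one subject's per-observer full volumes."""
    observers = tuple(sorted(volumes_by_observer))
    vols = tuple(float(volumes_by_observer[o]) for o in observers)
    pair = {
        (a, b): pairwise_percent_difference(volumes_by_observer[a], volumes_by_observer[b])
        for a, b in itertools.combinations(observers, 2)
    }
    return InterobserverSummary(
        subject_id=subject_id,
        observer_ids=observers,
        volumes_cm3=vols,
        cv_pct=cv(vols),
        greatest_pct_diff=greatest_percent_difference(vols),
        pairwise_pct_diff=pair,
    )


def summarize_series_cohort(cohort: list[SliceSeries]) -> list[InterobserverSummary]:
    """Per-subject summaries from a cohort of slice series.

    Every subject must be traced by the same observer set.
    """
    by_subject: dict[str, dict[str, float]] = {}
    for s in cohort:
        by_subject.setdefault(s.subject_id, {})
        if s.observer_id in by_subject[s.subject_id]:
            raise DataError(
                f"duplicate series for subject={s.subject_id} observer={s.observer_id}"
            )
        by_subject[s.subject_id][s.observer_id] = full_volume(s)
    observer_sets = {frozenset(v) for v in by_subject.values()}
    if len(observer_sets) > 1:
        raise IncompleteCohortError(
            "subjects traced by different observer sets: "
            + ", ".join(
                f"{subj}: {sorted(obs)}" for subj, obs in sorted(by_subject.items())
            )
        )
    return [summarize_subject(subj, vols) for subj, vols in sorted(by_subject.items())]


def subject_table(summaries: list[InterobserverSummary]) -> pd.DataFrame:
    """One row per subject: volumes, CV, greatest and pairwise differences."""
    if not summaries:
        raise DataError("no subjects to summarize")
    rows = []
    for s in summaries:
        row = {"subject": s.subject_id}
        for obs, vol in zip(s.observer_ids, s.volumes_cm3):
            row[f"volume_{obs}_cm3"] = vol
        row["mean_volume_cm3"] = float(np.mean(s.volumes_cm3))
        row["cv_pct"] = s.cv_pct
        row["greatest_pct_diff"] = s.greatest_pct_diff
        for (a, b), d in s.pairwise_pct_diff.items():
            row[f"pct_diff_{a}_{b}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(summaries: list[InterobserverSummary]) -> pd.DataFrame:
    """Cohort mean +/- sample SD of each agreement statistic.

    Returns a one-row frame with ``mean_``/``sd_`` column pairs for the
    volume, the CV, the greatest percent difference and each observer
    pair.  With a single subject the SDs are reported as missing.
    """
    table = subject_table(summaries)
    n = len(table)
    stats_cols = ["cv_pct", "greatest_pct_diff"] + [
        c for c in table.columns if c.startswith("pct_diff_")
    ]
    out = {"n_subjects": n}
    all_vols = np.array([v for s in summaries for v in s.volumes_cm3])
    out["mean_volume_cm3"] = float(all_vols.mean())
    out["sd_volume_cm3"] = float(all_vols.std(ddof=1)) if all_vols.size > 1 else np.nan
    for c in stats_cols:
        out[f"mean_{c}"] = float(table[c].mean())
        out[f"sd_{c}"] = float(table[c].std(ddof=1)) if n > 1 else np.nan
    return pd.DataFrame([out])
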