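"""Slice-decimation study: errors of decimated volumetry across a cohort.

The study runs every "thickness-interval" sampling scheme over every
subject-by-observer series, compares each phase-offset estimate to the
*same* subject's and observer's full-slice volume via

    pct_diff = |V_dec - V_full| / V_full x 100

and summarises the error by interval group (mean +/- SD, plus the
greatest value pooled across thickness groups sharing an interval) and by
the number of slices actually used (maximum per slice-count bin).

At the default design — 2.5 mm thickness with 5.0/7.5/10/15 mm intervals
and 3.75 mm with 7.5/11.25/15 mm, 8 subjects per thickness, 3 observers —
the per-observer group sizes are 16/24/32/48 and 16/24/32, i.e. 192 rows
per observer and 576 in total, alongside 48 full-volume measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, IncompleteCohortError
from . import interobserver as iobs
from .series import SliceSeries
from .volumetry import (
    DecimationScheme,
    _fmt_mm,
    full_volume,
    measure_all,
)

#: default slice-count bin cut points: <10, 10-14, 15-19, 20-24, >=25
DEFAULT_BIN_EDGES = (10, 15, 20, 25)

#: reference line used in the study's accept/reject reading of the plots
ACCEPTABLE_PCT_DIFF = 5.0


def default_groups() -> tuple[DecimationScheme, ...]:
    """The seven decimated groups plus the two full groups of the default design."""
    groups = []
    for t_mm, intervals_mm in ((2.5, (5.0, 7.5, 10.0, 15.0)), (3.75, (7.5, 11.25, 15.0))):
        groups.append(DecimationScheme(t_mm / 10.0, t_mm / 10.0))  # full
        for i_mm in intervals_mm:
            groups.append(DecimationScheme(t_mm / 10.0, i_mm / 10.0))
    return tuple(groups)


def bin_label(lo: int | None, hi: int | None) -> str:
    if lo is None:
        return f"<{hi}"
    if hi is None:
        return f">={lo}"
    return f"{lo}-{hi - 1}"


def make_bins(edges=DEFAULT_BIN_EDGES) -> list[tuple[int, int | None, str]]:
    """Half-open slice-count bins [lo, hi) from ascending cut points.

    ``edges = (10, 15, 20, 25)`` yields <10, 10-14, 15-19, 20-24, >=25 —
    a contiguous partition of the positive integers (the last bin is
    closed below at the final edge).
    """
    edges = tuple(int(e) for e in edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigError("bin edges must be strictly increasing")
    if edges[0] < 2:
        raise ConfigError("first bin edge must be >= 2")
    bins: list[tuple[int, int | None, str]] = [(1, edges[0], bin_label(None, edges[0]))]
    for lo, hi in zip(edges, edges[1:]):
        bins.append((lo, hi, bin_label(lo, hi)))
    bins.append((edges[-1], None, bin_label(edges[-1], None)))
    return bins


@dataclass(frozen=True)
class StudyDesign:
    """Sampling schemes, expected observer count, and slice-count bins."""

    groups: tuple[DecimationScheme, ...] = field(default_factory=default_groups)
    n_observers: int = 3
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ConfigError("n_observers must be >= 1")
        make_bins(self.bin_edges)  # validates
        labels = [g.group_label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate group labels in design: {labels}")
        if not self.groups:
            raise ConfigError("design must contain at least one group")

    @property
    def thicknesses(self) -> tuple[float, ...]:
        seen: list[float] = []
        for g in self.groups:
            if not any(abs(g.thickness_cm - t) < 1e-12 for t in seen):
                seen.append(g.thickness_cm)
        return tuple(seen)

    def decimated_groups(self) -> tuple[DecimationScheme, ...]:
        return tuple(g for g in self.groups if not g.is_full)


@dataclass(frozen=True)
class GroupSummary:
    """Percent-difference summary of one thickness-interval group."""

    group_label: str
    n_measurements: int
    n_per_observer: int
    mean_pct_diff: float
    sd_pct_diff: float


@dataclass(frozen=True)
class BinSummary:
    """Greatest percent difference among measurements in one slice-count bin."""

    bin_label: str
    n_measurements: int
    greatest_pct_diff: float | None


def percent_difference(estimate: float, reference: float) -> float:
    """|estimate - reference| / reference x 100."""
    if reference <= 0:
        raise DataError("reference volume must be > 0")
    return float(abs(estimate - reference) / reference * 100.0)


def _index_cohort(cohort: list[SliceSeries], design: StudyDesign):
    """Validate the subject x observer grid and thickness coverage."""
    by_subject: dict[str, dict[str, SliceSeries]] = {}
    for s in cohort:
        slot = by_subject.setdefault(s.subject_id, {})
        if s.observer_id in slot:
            raise DataError(
                f"duplicate series for subject={s.subject_id} observer={s.observer_id}"
            )
        slot[s.observer_id] = s
    if not by_subject:
        raise DataError("empty cohort")
    observers = sorted({o for slot in by_subject.values() for o in slot})
    missing = [
        (subj, obs)
        for subj, slot in sorted(by_subject.items())
        for obs in observers
        if obs not in slot
    ]
    if missing:
        raise IncompleteCohortError(
            "missing subject/observer combinations: "
            + ", ".join(f"{s}/{o}" for s, o in missing)
        )
    if len(observers) != design.n_observers:
        raise IncompleteCohortError(
            f"cohort has {len(observers)} observers {observers}, "
            f"design expects {design.n_observers}"
        )
    for subj, slot in sorted(by_subject.items()):
        for obs, series in sorted(slot.items()):
            if not any(
                abs(series.thickness_cm - t) < 1e-12 for t in design.thicknesses
            ):
                raise DataError(
                    f"subject={subj} observer={obs}: thickness "
                    f"{series.thickness_cm} cm matches no design group"
                )
    return by_subject, observers


def run_study(cohort: list[SliceSeries], design: StudyDesign | None = None) -> "StudyResults":
    """Run the full decimation study over a complete cohort.

    Every decimated measurement is compared to the full volume of the same
    subject traced by the same observer ("the corresponding full volume").
    """
    design = design if design is not None else StudyDesign()
    by_subject, observers = _index_cohort(cohort, design)

    full_rows, meas_rows = [], []
    for subj, slot in sorted(by_subject.items()):
        for obs in observers:
            series = slot[obs]
            v_full = full_volume(series)
            full_label = next(
                (
                    g.group_label
                    for g in design.groups
                    if g.is_full and abs(g.thickness_cm - series.thickness_cm) < 1e-12
                ),
                f"{_fmt_mm(series.thickness_cm)}-full",
            )
            full_rows.append(
                {
                    "subject": subj,
                    "observer": obs,
                    "group": full_label,
                    "thickness_mm": series.thickness_cm * 10.0,
                    "n_slices": series.n_slices,
                    "volume_cm3": v_full,
                }
            )
            for scheme in design.decimated_groups():
                if abs(scheme.thickness_cm - series.thickness_cm) > 1e-12:
                    continue
                for m in measure_all(series, scheme):
                    meas_rows.append(
                        {
                            "subject": subj,
                            "observer": obs,
                            "group": m.group_label,
                            "thickness_mm": m.thickness_cm * 10.0,
                            "interval_mm": m.interval_cm * 10.0,
                            "phase": m.phase,
                            "n_used": m.n_used,
                            "n_total": m.n_total,
                            "volume_cm3": m.volume_cm3,
                            "full_volume_cm3": v_full,
                            "pct_diff": percent_difference(m.volume_cm3, v_full),
                        }
                    )
    measurements = pd.DataFrame(meas_rows)
    if len(measurements):
        measurements["pct_diff_rounded"] = measurements["pct_diff"].round(1)
    return StudyResults(
        design=design,
        measurements=measurements,
        full_volumes=pd.DataFrame(full_rows),
        _cohort=list(cohort),
    )


@dataclass
class StudyResults:
    """Tables and summaries produced by :func:`run_study`.

    ``measurements`` has one row per decimated measurement (phase offset x
    group x observer x subject) including its percent difference from the
    corresponding full volume; ``full_volumes`` has one row per subject x
    observer full-slice measurement.
    """

    design: StudyDesign
    measurements: pd.DataFrame
    full_volumes: pd.DataFrame
    _cohort: list[SliceSeries] = field(repr=False, default_factory=list)

    # ---------------- group-level summaries ----------------

    def group_summaries(self, per_observer: bool = False) -> list[GroupSummary]:
        """Mean +/- sample SD of pct_diff per group, in design order.

        With ``per_observer=True`` each (group, observer) cell is
        summarised separately (the two readings of a pooled-vs-per-observer
        scatter are both available).
        """
        out = []
        order = [g.group_label for g in self.design.decimated_groups()]
        n_obs = self.design.n_observers
        if per_observer:
            for label in order:
                sub = self.measurements[self.measurements["group"] == label]
                for obs, grp in sub.groupby("observer", sort=True):
                    out.append(
                        GroupSummary(
                            group_label=f"{label}/{obs}",
                            n_measurements=len(grp),
                            n_per_observer=len(grp),
                            mean_pct_diff=float(grp["pct_diff"].mean()),
                            sd_pct_diff=float(grp["pct_diff"].std(ddof=1)),
                        )
                    )
            return out
        for label in order:
            grp = self.measurements[self.measurements["group"] == label]
            out.append(
                GroupSummary(
                    group_label=label,
                    n_measurements=len(grp),
                    n_per_observer=len(grp) // n_obs,
                    mean_pct_diff=float(grp["pct_diff"].mean()),
                    sd_pct_diff=float(grp["pct_diff"].std(ddof=1)),
                )
            )
        return out

    def group_summary(self, per_observer: bool = False) -> pd.DataFrame:
        rows = [
            {
                "group": g.group_label,
                "n_measurements": g.n_measurements,
                "n_per_observer": g.n_per_observer,
                "mean_pct_diff": g.mean_pct_diff,
                "sd_pct_diff": g.sd_pct_diff,
            }
            for g in self.group_summaries(per_observer=per_observer)
        ]
        return pd.DataFrame(rows)

    def interval_summary(self) -> pd.DataFrame:
        """Greatest pct_diff per slice interval, pooling thickness groups.

        Groups sharing an interval (e.g. 2.5-7.5 and 3.75-7.5 at 7.5 mm)
        are pooled before taking the maximum.
        """
        rows = []
        for interval, grp in self.measurements.groupby("interval_mm", sort=True):
            rows.append(
                {
                    "interval_mm": float(interval),
                    "groups": ",".join(sorted(grp["group"].unique())),
                    "n_measurements": len(grp),
                    "greatest_pct_diff": float(grp["pct_diff"].max()),
                }
            )
        return pd.DataFrame(rows)

    # ---------------- slice-count bins ----------------

    def bin_summaries(self) -> list[BinSummary]:
        return bin_by_slice_count(self.measurements, self.design.bin_edges)

    def bin_summary(self) -> pd.DataFrame:
        rows = [
            {
                "bin": b.bin_label,
                "n_measurements": b.n_measurements,
                "greatest_pct_diff": (
                    np.nan if b.greatest_pct_diff is None else b.greatest_pct_diff
                ),
            }
            for b in self.bin_summaries()
        ]
        return pd.DataFrame(rows)

    # ---------------- interobserver agreement ----------------

    def interobserver_summaries(self) -> list[iobs.InterobserverSummary]:
        return iobs.summarize_series_cohort(self._cohort)

    def interobserver_table(self) -> pd.DataFrame:
        return iobs.subject_table(self.interobserver_summaries())

    def interobserver_cohort(self) -> pd.DataFrame:
        return iobs.summarize_cohort(self.interobserver_summaries())

    # ---------------- presentation ----------------

    def summary(self) -> str:
        """Human-readable study report (percentages to 1 decimal)."""
        lines = []
        co = self.interobserver_cohort().iloc[0]
        lines.append(
            f"Cohort: {int(co['n_subjects'])} subjects x "
            f"{self.design.n_observers} observers "
            f"({len(self.full_volumes)} full-volume measurements)"
        )
        lines.append(
            f"Mean full hepatic volume: {co['mean_volume_cm3']:.1f} "
            f"(+/-{co['sd_volume_cm3']:.1f}) cm^3"
        )
        lines.append(
            f"Interobserver CV: {co['mean_cv_pct']:.1f} (+/-{co['sd_cv_pct']:.1f})%; "
            f"greatest pct diff: {co['mean_greatest_pct_diff']:.1f} "
            f"(+/-{co['sd_greatest_pct_diff']:.1f})%"
        )
        lines.append(f"Decimated measurements: {len(self.measurements)}")
        lines.append("Percent difference vs corresponding full volume, by group:")
        for g in self.group_summaries():
            lines.append(
                f"  {g.group_label:>10}: {g.mean_pct_diff:4.1f} (+/-{g.sd_pct_diff:.1f})% "
                f"[n={g.n_measurements}, {g.n_per_observer}/observer]"
            )
        lines.append("Greatest percent difference by slice interval:")
        for _, r in self.interval_summary().iterrows():
            lines.append(
                f"  {r['interval_mm']:g} mm: {r['greatest_pct_diff']:.1f}%  ({r['groups']})"
            )
        lines.append("Greatest percent difference by number of slices used:")
        for b in self.bin_summaries():
            val = "n/a" if b.greatest_pct_diff is None else f"{b.greatest_pct_diff:.1f}%"
            lines.append(f"  {b.bin_label:>6}: {val}  [n={b.n_measurements}]")
        return "\n".join(lines)

    def plot_by_interval(self, ax=None, threshold: float = ACCEPTABLE_PCT_DIFF):
        """Scatter of pct_diff per group with the acceptability line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        order = [g.group_label for g in self.design.decimated_groups()]
        pos = {label: i for i, label in enumerate(order)}
        x = self.measurements["group"].map(pos)
        ax.scatter(x, self.measurements["pct_diff"], s=12, alpha=0.6)
        ax.axhline(threshold, ls="--", color="crimson", lw=1)
        ax.set_xticks(range(len(order)), order, rotation=45, ha="right")
        ax.set_xlabel("thickness-interval group (mm)")
        ax.set_ylabel("percent difference from full volume (%)")
        return ax

    def plot_by_slice_count(self, ax=None, threshold: float = ACCEPTABLE_PCT_DIFF):
        """Scatter of pct_diff against slices used with the acceptability line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        ax.scatter(self.measurements["n_used"], self.measurements["pct_diff"], s=12, alpha=0.6)
        ax.axhline(threshold, ls="--", color="crimson", lw=1)
        ax.set_xlabel("number of slices used")
        ax.set_ylabel("percent difference from full volume (%)")
        return ax

    def to_csvs(self, outdir) -> dict[str, str]:
        """Write all study tables into ``outdir``; returns name -> path."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "measurements": self.measurements,
            "full_volumes": self.full_volumes,
            "group_summary": self.group_summary(),
            "group_summary_per_observer": self.group_summary(per_observer=True),
            "interval_greatest": self.interval_summary(),
            "bin_summary": self.bin_summary(),
            "interobserver_subjects": self.interobserver_table(),
            "interobserver_cohort": self.interobserver_cohort(),
        }
        paths = {}
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        return paths


def bin_by_slice_count(
    measurements: pd.DataFrame, edges=DEFAULT_BIN_EDGES
) -> list[BinSummary]:
    """Assign measurements to slice-count bins by ``n_used`` and report maxima.

    Each measurement falls in exactly one bin; empty bins are reported with
    n = 0 and no maximum.
    """
    if len(measurements) and (measurements["n_used"] < 1).any():
        raise DataError("n_used must be >= 1 for all measurements")
    out = []
    for lo, hi, label in make_bins(edges):
        mask = measurements["n_used"] >= lo
        if hi is not None:
            mask &= measurements["n_used"] < hi
        sub = measurements[mask]
        out.append(
            BinSummary(
                bin_label=label,
                n_measurements=len(sub),
                greatest_pct_diff=float(sub["pct_diff"].max()) if len(sub) else None,
            )
        )
    return out


class DecimationStudy:
    """Thin object wrapper: ``DecimationStudy(cohort, design).run()``."""

    def __init__(self, cohort: list[SliceSeries], design: StudyDesign | None = None):
        self.cohort = list(cohort)
        self.design = design if design is not None else StudyDesign()

    def run(self) -> StudyResults:
        return run_study(self.cohort, self.design)
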