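"""Synthetic canine-liver phantom cohort generator.

The generator emulates the cohort structure of a two-arm CT volumetry
study: ``n_subjects_per_thickness`` subjects per slice thickness (default
8 at 2.5 mm and 8 at 3.75 mm), each with a liver spanning 36-63 slices and
a smooth, strictly positive, unimodal cross-sectional area profile whose
summed volume is drawn so that the cohort mean/SD land near 722/281 cm^3.

The area-profile family is a scaled Beta density over the slice axis:
with peak-position fraction ``p`` and sharpness ``s``, the profile weights
are ``Beta(1 + p*s, 1 + (1-p)*s)`` evaluated at slice midpoints and
normalised to sum to one, then scaled so the slice sum times thickness
equals the drawn target volume exactly.  ``s = 0`` degenerates to a
constant profile.

Observer tracing variability is multiplicative lognormal: observer ``o``
scales every area by ``exp(b_o + e_s)`` with a per-observer systematic
bias ``b_o ~ N(0, per_observer_bias_sd)`` and independent per-slice jitter
``e_s ~ N(0, per_slice_noise_sd)``.  :func:`calibrate_observer_bias`
searches the bias SD so the cohort-mean interobserver volume CV hits a
target (default 2.5%).

Randomness is stream-split from one root seed, subject-major then
observer, so adding observers never perturbs subject profiles.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

from .errors import ConfigError, DataError, InfeasibleSpecError
from .series import MaskVolume, SliceSeries

#: per-observer systematic bias SD frozen from calibrate_observer_bias()
#: at the default per-slice jitter, targeting a 2.5% cohort-mean volume CV.
DEFAULT_BIAS_SD = 0.026972

#: per-slice fractional tracing jitter SD (lognormal sigma)
DEFAULT_SLICE_NOISE_SD = 0.05


@dataclass(frozen=True)
class ObserverNoiseSpec:
    """Multiplicative lognormal observer-noise model parameters."""

    n_observers: int = 3
    per_observer_bias_sd: float = DEFAULT_BIAS_SD
    per_slice_noise_sd: float = DEFAULT_SLICE_NOISE_SD

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ConfigError("n_observers must be >= 1")
        if self.per_observer_bias_sd < 0 or self.per_slice_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """All parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 8 subjects per thickness at
    0.25 and 0.375 cm, 36-63 liver-bearing slices, target volumes uniform
    on (235.0, 1209.4) cm^3 (mean 722.2, SD 281.3), and observer noise
    calibrated to a 2.5% cohort-mean volume CV.
    """

    n_subjects_per_thickness: int = 8
    thicknesses: tuple[float, ...] = (0.25, 0.375)
    slice_count_range: tuple[int, int] = (36, 63)
    target_volume_range: tuple[float, float] = (235.0, 1209.4)
    peak_position_range: tuple[float, float] = (0.30, 0.60)
    sharpness_range: tuple[float, float] = (3.0, 10.0)
    edge_floor: float = 0.02
    max_slice_area_cm2: float = 400.0
    observer_noise: ObserverNoiseSpec = field(default_factory=ObserverNoiseSpec)
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_subjects_per_thickness < 1:
            raise ConfigError("n_subjects_per_thickness must be >= 1")
        if not self.thicknesses or any(t <= 0 for t in self.thicknesses):
            raise ConfigError("all thicknesses must be > 0")
        lo, hi = self.slice_count_range
        if lo < 2 or hi < lo:
            raise ConfigError("slice_count_range must satisfy 2 <= min <= max")
        vlo, vhi = self.target_volume_range
        if vlo <= 0 or vhi < vlo:
            raise ConfigError("target_volume_range must be positive and ordered")
        plo, phi = self.peak_position_range
        if not (0 < plo <= phi < 1):
            raise ConfigError("peak_position_range must lie strictly inside (0, 1)")
        slo, shi = self.sharpness_range
        if slo < 0 or shi < slo:
            raise ConfigError("sharpness_range must be non-negative and ordered")
        if not (0 <= self.edge_floor < 1):
            raise ConfigError("edge_floor must lie in [0, 1)")
        if self.max_slice_area_cm2 <= 0:
            raise ConfigError("max_slice_area_cm2 must be > 0")

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_per_thickness * len(self.thicknesses)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thicknesses"] = list(self.thicknesses)
        d["slice_count_range"] = list(self.slice_count_range)
        d["target_volume_range"] = list(self.target_volume_range)
        d["peak_position_range"] = list(self.peak_position_range)
        d["sharpness_range"] = list(self.sharpness_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        noise = d.pop("observer_noise", None)
        known = set(cls.__dataclass_fields__)
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown phantom config keys: {unknown}")
        kwargs: dict = {}
        for key in ("thicknesses",):
            if key in d:
                kwargs[key] = tuple(float(v) for v in d.pop(key))
        for key in ("slice_count_range",):
            if key in d:
                kwargs[key] = tuple(int(v) for v in d.pop(key))
        for key in ("target_volume_range", "peak_position_range", "sharpness_range"):
            if key in d:
                kwargs[key] = tuple(float(v) for v in d.pop(key))
        kwargs.update(d)
        if noise is not None:
            if isinstance(noise, ObserverNoiseSpec):
                kwargs["observer_noise"] = noise
            else:
                nk = set(noise) - set(ObserverNoiseSpec.__dataclass_fields__)
                if nk:
                    raise ConfigError(f"unknown observer_noise config keys: {sorted(nk)}")
                kwargs["observer_noise"] = ObserverNoiseSpec(**noise)
        return cls(**kwargs)


def _profile_weights(
    n_slices: int, peak_position: float, sharpness: float, edge_floor: float = 0.0
) -> np.ndarray:
    """Normalised unimodal profile weights on slice midpoints (sum to 1).

    ``edge_floor`` mixes in a uniform pedestal: the organ appears and
    disappears with a finite (not vanishing) cross-section, as a liver
    does at the diaphragm and at its caudal tip.  The mixture of a
    unimodal curve and a constant stays unimodal.
    """
    x = (np.arange(n_slices) + 0.5) / n_slices
    a = 1.0 + peak_position * sharpness
    b = 1.0 + (1.0 - peak_position) * sharpness
    w = stats.beta.pdf(x, a, b)
    w = (1.0 - edge_floor) * w / w.sum() + edge_floor / n_slices
    return w / w.sum()


def generate_subject_profile(
    spec: PhantomSpec,
    thickness_cm: float,
    rng: np.random.Generator,
    subject_id: str = "subject",
) -> SliceSeries:
    """Draw one noise-free subject area profile.

    The slice count is uniform on ``slice_count_range``, the profile is a
    Beta-shaped unimodal curve with randomly drawn peak position and
    sharpness, and the areas are scaled so the full volume equals a target
    drawn uniformly from ``target_volume_range``.
    """
    if not any(abs(thickness_cm - t) < 1e-12 for t in spec.thicknesses):
        raise ConfigError(
            f"thickness {thickness_cm} cm is not one of spec.thicknesses {spec.thicknesses}"
        )
    lo, hi = spec.slice_count_range
    n_slices = int(rng.integers(lo, hi + 1))
    volume = float(rng.uniform(*spec.target_volume_range))
    peak = float(rng.uniform(*spec.peak_position_range))
    sharp = float(rng.uniform(*spec.sharpness_range))
    weights = _profile_weights(n_slices, peak, sharp, spec.edge_floor)
    areas = volume * weights / thickness_cm
    peak_area = float(areas.max())
    if peak_area > spec.max_slice_area_cm2:
        raise InfeasibleSpecError(
            f"target volume {volume:.1f} cm^3 over {n_slices} slices of "
            f"{thickness_cm} cm requires a peak slice area of {peak_area:.1f} cm^2, "
            f"exceeding max_slice_area_cm2 = {spec.max_slice_area_cm2}"
        )
    return SliceSeries(
        subject_id=subject_id, observer_id="truth", thickness_cm=thickness_cm, areas_cm2=areas
    )


def observer_label(observer_index: int) -> str:
    """'A', 'B', 'C', ... (falls back to 'O<i>' past 26 observers)."""
    if 0 <= observer_index < 26:
        return string.ascii_uppercase[observer_index]
    return f"O{observer_index}"


def apply_observer(
    series: SliceSeries,
    noise: ObserverNoiseSpec,
    observer_index: int,
    rng: np.random.Generator,
) -> SliceSeries:
    """Simulate one observer's tracing of ``series``.

    Each area is multiplied by ``exp(b + e_s)``; with both SDs zero the
    output areas equal the input exactly.
    """
    if observer_index < 0 or observer_index >= noise.n_observers:
        raise ConfigError(
            f"observer_index {observer_index} out of range for {noise.n_observers} observers"
        )
    bias = rng.normal(0.0, noise.per_observer_bias_sd) if noise.per_observer_bias_sd > 0 else 0.0
    if noise.per_slice_noise_sd > 0:
        eps = rng.normal(0.0, noise.per_slice_noise_sd, size=series.n_slices)
    else:
        eps = np.zeros(series.n_slices)
    factors = np.exp(bias + eps)
    return series.with_areas(
        series.areas_cm2 * factors, observer_id=observer_label(observer_index)
    )


def generate_cohort(
    spec: PhantomSpec, include_truth: bool = False
) -> list[SliceSeries]:
    """Generate the full synthetic cohort: subjects x observers series.

    Subject ids are ``S01, S02, ...`` ordered thickness-major (all subjects
    of the first thickness first).  One root seed; each subject gets its
    own spawned stream, split again into one profile stream plus one stream
    per observer, so cohorts are bit-identical for identical (spec, seed)
    and observer count does not influence subject anatomy.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    cohort: list[SliceSeries] = []
    idx = 0
    for thickness in spec.thicknesses:
        for _ in range(spec.n_subjects_per_thickness):
            subject_id = f"S{idx + 1:02d}"
            streams = subject_seeds[idx].spawn(1 + spec.observer_noise.n_observers)
            profile = generate_subject_profile(
                spec, thickness, np.random.default_rng(streams[0]), subject_id=subject_id
            )
            if include_truth:
                cohort.append(profile)
            for o in range(spec.observer_noise.n_observers):
                cohort.append(
                    apply_observer(
                        profile,
                        spec.observer_noise,
                        o,
                        np.random.default_rng(streams[1 + o]),
                    )
                )
            idx += 1
    return cohort


def calibrate_observer_bias(
    target_cv_pct: float = 2.5,
    per_slice_noise_sd: float = DEFAULT_SLICE_NOISE_SD,
    spec: PhantomSpec | None = None,
    n_subjects: int = 4096,
    n_observers: int = 3,
    seed: int = 20230,
) -> float:
    """Find the per-observer bias SD giving a target cohort-mean volume CV.

    Simulates ``n_subjects`` profile shapes once (common random numbers),
    then solves for the bias SD by bracketed root finding on the smooth,
    monotone mapping bias SD -> mean per-subject sample CV of the
    ``n_observers`` volumes.  The volume scale cancels out of the CV, so
    only profile weights matter.
    """
    if target_cv_pct <= 0:
        raise ConfigError("target_cv_pct must be > 0")
    base = spec if spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    lo, hi = base.slice_count_range
    weights = []
    for _ in range(n_subjects):
        n = int(rng.integers(lo, hi + 1))
        peak = float(rng.uniform(*base.peak_position_range))
        sharp = float(rng.uniform(*base.sharpness_range))
        weights.append(_profile_weights(n, peak, sharp, base.edge_floor))
    z_bias = rng.standard_normal((n_subjects, n_observers))
    z_slice = [rng.standard_normal((n_observers, w.size)) for w in weights]

    def mean_cv(bias_sd: float) -> float:
        cvs = np.empty(n_subjects)
        for i, w in enumerate(weights):
            vols = np.exp(bias_sd * z_bias[i]) * (
                np.exp(per_slice_noise_sd * z_slice[i]) @ w
            )
            cvs[i] = vols.std(ddof=1) / vols.mean() * 100.0
        return float(cvs.mean())

    floor_cv = mean_cv(0.0)
    if floor_cv >= target_cv_pct:
        raise InfeasibleSpecError(
            f"per-slice noise alone yields a mean CV of {floor_cv:.2f}% "
            f">= target {target_cv_pct}%; reduce per_slice_noise_sd"
        )
    upper = 0.02
    while mean_cv(upper) < target_cv_pct:
        upper *= 2.0
        if upper > 2.0:
            raise InfeasibleSpecError("target CV unreachable with bias SD <= 2.0")
    return float(
        optimize.brentq(lambda s: mean_cv(s) - target_cv_pct, 0.0, upper, xtol=1e-5)
    )


def voxelize(
    series: SliceSeries,
    in_plane_pitch_mm: float = 1.0,
    rng: np.random.Generator | None = None,
) -> MaskVolume:
    """Rasterise a series as a stack of filled discs on a pixel grid.

    Each slice becomes a disc whose analytic area equals the series area;
    a pixel is foreground when its centre lies inside the disc, so the
    pixel-counted area differs from the target by at most on the order of
    the perimeter pixel count.  With ``rng`` given, the disc centre is
    jittered by up to half a pixel to decorrelate rasterisation error
    across slices.
    """
    if in_plane_pitch_mm <= 0:
        raise DataError("in_plane_pitch_mm must be > 0")
    areas_mm2 = series.areas_cm2 * 100.0
    positive = areas_mm2[areas_mm2 > 0]
    if positive.size and positive.min() < in_plane_pitch_mm**2:
        raise DataError(
            f"pitch {in_plane_pitch_mm} mm too coarse: smallest slice area "
            f"{positive.min():.2f} mm^2 spans less than one pixel"
        )
    radii = np.sqrt(areas_mm2 / np.pi)
    half = int(np.ceil(radii.max() / in_plane_pitch_mm)) + 2
    n_pix = 2 * half
    centers = (np.arange(n_pix) - half + 0.5) * in_plane_pitch_mm
    xx, yy = np.meshgrid(centers, centers, indexing="ij")
    voxels = np.zeros((series.n_slices, n_pix, n_pix), dtype=bool)
    for i, r in enumerate(radii):
        if r == 0:
            continue
        if rng is not None:
            cx, cy = rng.uniform(-0.5, 0.5, size=2) * in_plane_pitch_mm
        else:
            cx = cy = 0.0
        voxels[i] = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return MaskVolume(
        voxels=voxels,
        spacing_mm=(series.thickness_cm * 10.0, in_plane_pitch_mm, in_plane_pitch_mm),
        subject_id=series.subject_id,
    )


def save_mask_nifti(mask: MaskVolume, path) -> None:
    """Write a mask as NIfTI; voxel spacing goes into the affine zooms."""
    import nibabel as nib

    affine = np.diag([*mask.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def load_mask_nifti(path, subject_id: str | None = None) -> MaskVolume:
    """Read a binary mask from NIfTI; spacing is taken from the header."""
    import nibabel as nib
    from pathlib import Path

    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise DataError(f"{path}: NIfTI header has non-positive voxel spacing {zooms}")
    sid = subject_id if subject_id is not None else Path(path).stem.replace(".nii", "")
    return MaskVolume(
        voxels=np.asanyarray(img.dataobj) > 0, spacing_mm=zooms, subject_id=sid
    )
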