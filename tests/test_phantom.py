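"""Phantom cohort generator: determinism, constraints, noise and voxel round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hepvol
from hepvol.errors import ConfigError, DataError, InfeasibleSpecError
from hepvol.phantom import _profile_weights


def cohort_fingerprint(cohort):
    return [
        (s.subject_id, s.observer_id, s.thickness_cm, s.areas_cm2.tobytes())
        for s in cohort
    ]


class TestGeneratorDeterminism:
    def test_identical_spec_and_seed_bit_identical(self):
        spec = hepvol.PhantomSpec(seed=7)
        a = hepvol.generate_cohort(spec)
        b = hepvol.generate_cohort(hepvol.PhantomSpec(seed=7))
        assert cohort_fingerprint(a) == cohort_fingerprint(b)

    def test_different_seed_differs(self):
        a = hepvol.generate_cohort(hepvol.PhantomSpec(seed=7))
        b = hepvol.generate_cohort(hepvol.PhantomSpec(seed=8))
        assert cohort_fingerprint(a) != cohort_fingerprint(b)

    def test_observer_count_does_not_perturb_subject_profiles(self):
        # subject-major stream splitting: truth anatomy is invariant to n_observers
        def truths(n_obs):
            spec = hepvol.PhantomSpec(
                seed=3, observer_noise=hepvol.ObserverNoiseSpec(n_observers=n_obs)
            )
            return [
                s for s in hepvol.generate_cohort(spec, include_truth=True)
                if s.observer_id == "truth"
            ]

        assert cohort_fingerprint(truths(1)) == cohort_fingerprint(truths(3))


class TestSubjectProfiles:
    def test_postconditions_hold_across_seeds(self):
        spec = hepvol.PhantomSpec()
        for seed in range(5):
            for s in hepvol.generate_cohort(
                hepvol.PhantomSpec(seed=seed), include_truth=True
            ):
                if s.observer_id != "truth":
                    continue
                lo, hi = spec.slice_count_range
                assert lo <= s.n_slices <= hi
                assert np.all(s.areas_cm2 > 0)
                vlo, vhi = spec.target_volume_range
                assert vlo <= hepvol.full_volume(s) <= vhi
                # unimodal: increases to the peak, decreases after
                peak = int(np.argmax(s.areas_cm2))
                assert np.all(np.diff(s.areas_cm2[: peak + 1]) > 0)
                assert np.all(np.diff(s.areas_cm2[peak:]) < 0)

    def test_degenerate_shape_family_gives_constant_profile(self):
        spec = hepvol.PhantomSpec(
            slice_count_range=(40, 40), sharpness_range=(0.0, 0.0)
        )
        s = hepvol.generate_subject_profile(spec, 0.25, np.random.default_rng(1))
        assert s.n_slices == 40
        np.testing.assert_allclose(s.areas_cm2, s.areas_cm2[0])

    def test_monte_carlo_cohort_mean_volume(self):
        # 1000 draws: empirical mean within the configured target band
        spec = hepvol.PhantomSpec()
        rng = np.random.default_rng(12)
        vols = [
            hepvol.full_volume(hepvol.generate_subject_profile(spec, 0.25, rng))
            for _ in range(1000)
        ]
        lo, hi = spec.target_volume_range
        expected_mean = (lo + hi) / 2  # 722.2 by construction
        se = (hi - lo) / np.sqrt(12) / np.sqrt(1000)
        assert abs(np.mean(vols) - expected_mean) < 4 * se

    def test_wrong_thickness_rejected(self):
        spec = hepvol.PhantomSpec()
        with pytest.raises(ConfigError, match="thickness"):
            hepvol.generate_subject_profile(spec, 0.5, np.random.default_rng(0))

    def test_infeasible_volume_names_constraint(self):
        spec = hepvol.PhantomSpec(max_slice_area_cm2=5.0)
        with pytest.raises(InfeasibleSpecError, match="max_slice_area_cm2"):
            hepvol.generate_subject_profile(spec, 0.25, np.random.default_rng(0))

    @given(
        peak=st.floats(0.05, 0.95),
        sharp=st.floats(0.0, 30.0),
        n=st.integers(2, 80),
    )
    @settings(derandomize=True, max_examples=60)
    def test_profile_weights_positive_and_normalized(self, peak, sharp, n):
        w = _profile_weights(n, peak, sharp)
        assert np.all(w > 0)
        assert np.sum(w) == pytest.approx(1.0)


class TestObserverNoise:
    def test_zero_noise_is_identity(self, default_spec):
        s = hepvol.generate_subject_profile(
            default_spec, 0.25, np.random.default_rng(5)
        )
        noise = hepvol.ObserverNoiseSpec(
            n_observers=3, per_observer_bias_sd=0.0, per_slice_noise_sd=0.0
        )
        out = hepvol.apply_observer(s, noise, 0, np.random.default_rng(5))
        np.testing.assert_array_equal(out.areas_cm2, s.areas_cm2)
        assert out.observer_id == "A"
        assert out.thickness_cm == s.thickness_cm

    def test_pure_bias_scales_volume_by_common_factor(self, default_spec):
        s = hepvol.generate_subject_profile(
            default_spec, 0.25, np.random.default_rng(5)
        )
        noise = hepvol.ObserverNoiseSpec(
            n_observers=1, per_observer_bias_sd=0.1, per_slice_noise_sd=0.0
        )
        rng = np.random.default_rng(21)
        bias = np.random.default_rng(21).normal(0.0, 0.1)
        out = hepvol.apply_observer(s, noise, 0, rng)
        ratios = out.areas_cm2 / s.areas_cm2
        np.testing.assert_allclose(ratios, np.exp(bias), rtol=1e-12)
        assert hepvol.full_volume(out) == pytest.approx(
            np.exp(bias) * hepvol.full_volume(s), rel=1e-12
        )

    def test_calibrated_noise_brackets_target_cv(self):
        # default calibrated noise: mean per-subject volume CV in [1%, 4%]
        cvs = []
        for seed in range(8):
            cohort = hepvol.generate_cohort(hepvol.PhantomSpec(seed=seed))
            summaries = hepvol.summarize_series_cohort(cohort)
            cvs.extend(s.cv_pct for s in summaries)
        assert 1.0 < np.mean(cvs) < 4.0

    def test_calibration_routine_recovers_target(self):
        # small-n rerun of the packaged search lands near the frozen default
        sd = hepvol.calibrate_observer_bias(
            target_cv_pct=2.5, n_subjects=512, seed=77
        )
        assert sd == pytest.approx(hepvol.phantom.DEFAULT_BIAS_SD, rel=0.15)

    def test_slice_noise_floor_infeasibility(self):
        with pytest.raises(InfeasibleSpecError, match="per-slice"):
            hepvol.calibrate_observer_bias(
                target_cv_pct=0.1, per_slice_noise_sd=0.2, n_subjects=64
            )


class TestVoxelization:
    def test_disc_radius_and_area(self):
        # area 100 cm^2 -> disc radius ~56.42 mm; pixel count within 1%
        s = hepvol.SliceSeries("S", "A", 0.25, [100.0])
        mask = hepvol.voxelize(s, in_plane_pitch_mm=1.0)
        count = mask.voxels[0].sum()
        assert count == pytest.approx(10000.0, rel=0.01)  # mm^2 at 1 mm pitch

    def test_round_trip_volume_within_one_percent(self, default_spec):
        s = hepvol.generate_subject_profile(
            default_spec, 0.375, np.random.default_rng(9)
        )
        mask = hepvol.voxelize(s, in_plane_pitch_mm=1.0, rng=np.random.default_rng(1))
        back = hepvol.mask_to_series(mask)
        assert back.n_slices == s.n_slices
        assert hepvol.full_volume(back) == pytest.approx(
            hepvol.full_volume(s), rel=0.01
        )

    def test_pitch_too_coarse_rejected(self):
        s = hepvol.SliceSeries("S", "A", 0.25, [0.005])  # 0.5 mm^2
        with pytest.raises(DataError, match="too coarse"):
            hepvol.voxelize(s, in_plane_pitch_mm=1.0)

    def test_zero_length_series_unconstructible(self):
        with pytest.raises(DataError):
            hepvol.SliceSeries("S", "A", 0.25, [])

    def test_nifti_round_trip(self, tmp_path):
        s = hepvol.SliceSeries("S07", "A", 0.25, [20.0, 35.0, 22.0])
        mask = hepvol.voxelize(s, in_plane_pitch_mm=1.0)
        path = tmp_path / "S07.nii.gz"
        hepvol.save_mask_nifti(mask, path)
        back = hepvol.load_mask_nifti(path)
        np.testing.assert_array_equal(back.voxels, mask.voxels)
        assert back.spacing_mm == pytest.approx(mask.spacing_mm)
        assert back.subject_id == "S07"


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"thicknesses": (0.25, -0.1)},
            {"slice_count_range": (1, 40)},
            {"slice_count_range": (40, 30)},
            {"target_volume_range": (-1.0, 10.0)},
            {"peak_position_range": (0.0, 0.5)},
            {"n_subjects_per_thickness": 0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            hepvol.PhantomSpec(**kwargs)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ConfigError):
            hepvol.ObserverNoiseSpec(n_observers=0)
        with pytest.raises(ConfigError):
            hepvol.ObserverNoiseSpec(per_slice_noise_sd=-0.1)

    def test_dict_round_trip_lossless(self, default_spec):
        back = hepvol.PhantomSpec.from_dict(default_spec.to_dict())
        assert back == default_spec

    def test_unknown_keys_listed(self):
        with pytest.raises(ConfigError, match="typo_key"):
            hepvol.PhantomSpec.from_dict({"typo_key": 1})
        with pytest.raises(ConfigError, match="bad_noise_key"):
            hepvol.PhantomSpec.from_dict({"observer_noise": {"bad_noise_key": 1}})
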