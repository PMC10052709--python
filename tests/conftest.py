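import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import hepvol


@pytest.fixture(scope="session")
def default_spec() -> hepvol.PhantomSpec:
    return hepvol.PhantomSpec()


@pytest.fixture(scope="session")
def default_cohort(default_spec) -> list[hepvol.SliceSeries]:
    """The default-seed 16-subject x 3-observer synthetic cohort."""
    return hepvol.generate_cohort(default_spec)


@pytest.fixture(scope="session")
def default_results(default_cohort) -> hepvol.StudyResults:
    return hepvol.run_study(default_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def random_series(rng, n, thickness_cm=0.25, subject="S", observer="A"):
    """A valid random series: positive areas, positive ends."""
    areas = rng.uniform(0.5, 120.0, size=n)
    return hepvol.SliceSeries(
        subject_id=subject, observer_id=observer,
        thickness_cm=thickness_cm, areas_cm2=areas,
    )


def constant_cohort(n_per_thickness=2, n_slices=40, area=10.0, observers=("A", "B", "C")):
    """Zero-noise constant-profile cohort: every estimator is exact on it."""
    cohort = []
    i = 0
    for t in (0.25, 0.375):
        for _ in range(n_per_thickness):
            i += 1
            for obs in observers:
                cohort.append(
                    hepvol.SliceSeries(
                        subject_id=f"S{i:02d}", observer_id=obs,
                        thickness_cm=t, areas_cm2=np.full(n_slices, area),
                    )
                )
    return cohort
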