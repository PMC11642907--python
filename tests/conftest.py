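import numpy as np
import pytest

from detcon.synthetic import CohortConfig, CohortTimeCourses, generate_cohort

# Reduced study scale used throughout the unit tests: same temporal structure
# as the full design (jittered cycles, AR(1) noise, latent factors) but fewer
# subjects/nodes/volumes so a full pipeline pass stays in seconds.
SMALL = dict(n_subjects=12, n_nodes=8, n_time=240, n_cycles=9)

# Calibration scale: default amplitudes, full run length, enough subjects for
# stable cohort-level means.
CALIB = dict(n_subjects=20, n_nodes=12, n_time=488, n_cycles=24)


@pytest.fixture(scope="session")
def small_cohort() -> CohortTimeCourses:
    return generate_cohort(CohortConfig(seed=7, **SMALL))


@pytest.fixture(scope="session")
def paper_scale_cohort() -> CohortTimeCourses:
    """One cohort at the full study dimensions (50 x 34 x 488 x 2)."""
    return generate_cohort(CohortConfig(seed=1))


def copycat_cohort(base: CohortTimeCourses) -> CohortTimeCourses:
    """Cohort whose retest session is an exact copy of the test session."""
    data = base.data.copy()
    data[..., 1] = data[..., 0]
    rts = base.response_times.copy()
    rts[..., 1] = rts[..., 0]
    return CohortTimeCourses(
        data=data, config=base.config, nuisance=base.nuisance, response_times=rts
    )


def ar1_series(n, phi, rng, size=()):
    """Stationary unit-variance AR(1) sample(s)."""
    x = np.empty(size + (n,))
    x[..., 0] = rng.normal(0, 1, size)
    innov = rng.normal(0, np.sqrt(1 - phi**2), size + (n - 1,))
    for t in range(1, n):
        x[..., t] = phi * x[..., t - 1] + innov[..., t - 1]
    return x


def correlated_ar1_pair(n, phi, true_r, rng):
    """Two AR(1) series with population correlation ``true_r``."""
    f, e1, e2 = ar1_series(n, phi, rng, size=(3,))
    a = np.sqrt(true_r)
    x = a * f + np.sqrt(1 - true_r) * e1
    y = a * f + np.sqrt(1 - true_r) * e2
    return x, y
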