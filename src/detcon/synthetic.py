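"""Synthetic test/retest cohorts of task-fMRI node time courses.

The generator emulates the study design the analysis pipeline assumes: a slow
event-related working-memory task whose cycle repeats 24 times with a
jittered ~12 s pause, measured twice (test and retest, 488 volumes at
TR = 1.24 s) on 50 subjects over 34 network nodes.  Each node time course is

    data[s, n, t, sess] = g_s * a_n * regressor_sess(t)
                          + latent network factors + nuisance leakage
                          + AR(1) noise,

where the subject gain g_s is drawn from a right-skewed distribution with a
zero-gain mass (producing non-reproducing subjects and a small fraction of
negative test-retest reliabilities), the node profile a_n spreads reliability
across regions, session-specific latent factors induce inter-node
connectivity beyond the shared task response, and the AR(1) noise gives the
serial dependence that prewhitening and block bootstrap are meant to handle.
Behavioral response times (24 Stroop + 24 memory items per session) are
generated with a per-subject test-retest reliability stochastically coupled
to that subject's time-course reliability.

Default amplitudes are calibrated so that the cohort-mean within-subject
time-course reliability is ~0.19 and observed connectivity exceeds the
reliability-limited (detectable) connectivity, as in real task-fMRI cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CohortConfig",
    "CohortTimeCourses",
    "generate_task_regressor",
    "generate_cohort",
    "generate_response_times",
    "double_gamma_hrf",
]

N_RT_ITEMS = 48  # 24 Stroop + 24 memory responses per session


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Durations are in seconds; gains are dimensionless multipliers of the
    unit-peak task regressor relative to unit-scale innovation noise.
    """

    n_subjects: int = 50
    n_nodes: int = 34
    n_time: int = 488
    tr_seconds: float = 1.24
    n_cycles: int = 24
    cycle_active_seconds: float = 10.0
    pause_seconds: float = 12.0
    pause_jitter_seconds: float = 2.0  # pauses uniform on pause +/- jitter
    # subject task-signal gain: Gamma(shape, scale) with a zero-gain fraction
    subject_gain_shape: float = 4.0
    subject_gain_scale: float = 0.44
    zero_gain_fraction: float = 0.08
    # per-node gain multipliers; None -> linspace(0.5, 1.5)
    node_amplitude_profile: Sequence[float] | None = None
    ar1_phi: float = 0.4
    noise_sigma: float = 1.0
    # latent "network" factors shared across nodes within a session
    n_latent: int = 3
    latent_loading_scale: float = 0.7
    n_nuisance: int = 12  # 5 white-matter + 5 ventricle + 2 motion components
    nuisance_leak: float = 0.25
    rt_coupling: float = 0.46
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_nodes", "n_time", "n_cycles"):
            if getattr(self, name) < 0 or (name != "n_cycles" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(
            [
                self.subject_gain_shape,
                self.subject_gain_scale,
                self.ar1_phi,
                self.noise_sigma,
                self.latent_loading_scale,
            ]
        ).all():
            raise ValueError("gain and noise parameters must be finite")
        if not abs(self.ar1_phi) < 1:
            raise ValueError(f"|ar1_phi| must be < 1, got {self.ar1_phi}")
        if not -1.0 <= self.rt_coupling <= 1.0:
            raise ValueError(f"rt_coupling must be in [-1, 1], got {self.rt_coupling}")
        if not 0.0 <= self.zero_gain_fraction <= 1.0:
            raise ValueError("zero_gain_fraction must be in [0, 1]")
        total = self.n_time * self.tr_seconds
        needed = self.n_cycles * (
            self.cycle_active_seconds + self.pause_seconds + self.pause_jitter_seconds
        )
        if needed > total:
            raise ValueError(
                f"{self.n_cycles} task cycles of {self.cycle_active_seconds}s plus "
                f"pauses up to {self.pause_seconds + self.pause_jitter_seconds}s "
                f"need {needed:.1f}s but the run lasts only {total:.1f}s"
            )

    def node_profile(self) -> np.ndarray:
        if self.node_amplitude_profile is not None:
            prof = np.asarray(self.node_amplitude_profile, dtype=float)
            if prof.size != self.n_nodes:
                raise ValueError("node_amplitude_profile length must equal n_nodes")
            return prof
        if self.n_nodes == 1:
            return np.ones(1)
        return np.linspace(0.5, 1.5, self.n_nodes)


@dataclass
class CohortTimeCourses:
    """One synthetic cohort: node signals, nuisance series and response times.

    ``data`` is [subject, node, time, session] with session 0 = test and
    session 1 = retest; ``nuisance`` is [subject, regressor, time, session];
    ``response_times`` is [subject, item, session] with Stroop responses on
    the odd item positions (1-based) and memory responses on the even ones.
    """

    data: np.ndarray
    config: CohortConfig
    nuisance: np.ndarray
    response_times: np.ndarray
    subject_gains: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    latent_loadings: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.isnan(self.data).any():
            raise ValueError("cohort data contains missing values")
        if (self.data.std(axis=2) == 0).any():
            raise ValueError("cohort contains a constant time course")
        if self.response_times.shape[1] != N_RT_ITEMS:
            raise ValueError(
                f"expected {N_RT_ITEMS} response-time items per session, "
                f"got {self.response_times.shape[1]}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response at times t (s).

    Peak around 5 s with a shallow undershoot near 15 s; any smooth unimodal
    kernel would serve the statistics downstream, this is the conventional
    choice.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x: np.ndarray, a: float) -> np.ndarray:
        return np.exp((a - 1) * np.log(x) - x - gammaln(a))

    h[pos] = gpdf(tp, 6.0) - gpdf(tp, 16.0) / 6.0
    return h


def _session_regressor(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Expected BOLD response of one session: jittered cycle onsets * HRF."""
    n, tr = config.n_time, config.tr_seconds
    if config.n_cycles == 0:
        return np.zeros(n)
    # Jittered pauses without cumulative drift: every cycle occupies a fixed
    # slot of (active + mean pause) seconds and the jitter shifts the onset
    # within its slot, so inter-stimulus intervals vary on
    # pause +/- jitter while test and retest schedules stay aligned.
    period = config.cycle_active_seconds + config.pause_seconds
    jitter = rng.uniform(
        -config.pause_jitter_seconds / 2,
        config.pause_jitter_seconds / 2,
        size=config.n_cycles,
    )
    box = np.zeros(n)
    for c in range(config.n_cycles):
        onset = max(0.0, c * period + jitter[c])
        i0 = int(round(onset / tr))
        i1 = int(round((onset + config.cycle_active_seconds) / tr))
        box[i0 : min(i1, n)] = 1.0
    hrf = double_gamma_hrf(np.arange(0, 32.0, tr))
    reg = np.convolve(box, hrf)[:n]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def generate_task_regressor(config: CohortConfig) -> np.ndarray:
    """Canonical expected-response time course for one run (unit peak).

    24 cycle blocks (by default) convolved with the hemodynamic impulse
    response, pauses jittered by the config-seeded RNG.  Deterministic given
    (config, seed).
    """
    return _session_regressor(config, np.random.default_rng(config.seed))


def _ar1_noise(
    shape: tuple[int, ...], phi: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """AR(1) series along the last axis, stationary start, innovation sd sigma."""
    out = np.empty(shape)
    n = shape[-1]
    stat_sd = sigma / np.sqrt(1.0 - phi**2) if phi != 0 else sigma
    out[..., 0] = rng.normal(0.0, stat_sd, shape[:-1])
    innov = rng.normal(0.0, sigma, shape[:-1] + (n - 1,))
    for t in range(1, n):
        out[..., t] = phi * out[..., t - 1] + innov[..., t - 1]
    return out


def _subject_gains(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    g = rng.gamma(config.subject_gain_shape, config.subject_gain_scale, config.n_subjects)
    zero = rng.random(config.n_subjects) < config.zero_gain_fraction
    g[zero] = 0.0
    return g


def generate_cohort(config: CohortConfig) -> CohortTimeCourses:
    """Generate a full test/retest cohort, reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    S, N, T = config.n_subjects, config.n_nodes, config.n_time
    gains = _subject_gains(config, rng)
    node_gain = config.node_profile()
    # First factor: global positive loading (arousal/physiology-like), the
    # rest random-sign network structure.  Positive-dominant loadings keep
    # the fraction of robustly negative paths small, as in task cohorts.
    if config.n_latent > 0:
        loadings = rng.normal(0.0, 0.5 * config.latent_loading_scale, (N, config.n_latent))
        loadings[:, 0] = rng.normal(
            config.latent_loading_scale, 0.3 * config.latent_loading_scale, N
        )
    else:
        loadings = np.zeros((N, 0))
    if (
        config.noise_sigma == 0
        and config.n_latent > 0
        and np.linalg.matrix_rank(loadings) < min(N, config.n_latent)
    ):
        raise ValueError("rank-deficient latent loadings with zero noise: degenerate covariance")
    nuis_weights = rng.normal(0.0, 1.0, (N, config.n_nuisance))

    regs = np.stack(
        [_session_regressor(config, rng) for _ in range(2)], axis=-1
    )  # [time, session]

    data = np.empty((S, N, T, 2))
    nuisance = np.empty((S, config.n_nuisance, T, 2))
    for s in range(S):
        for sess in range(2):
            task = gains[s] * node_gain[:, None] * regs[None, :, sess]
            factors = (
                _ar1_noise((config.n_latent, T), config.ar1_phi, 1.0, rng)
                if config.n_latent > 0
                else np.zeros((0, T))
            )
            nuis = _ar1_noise((config.n_nuisance, T), config.ar1_phi, 1.0, rng)
            noise = _ar1_noise((N, T), config.ar1_phi, config.noise_sigma, rng)
            data[s, :, :, sess] = (
                task
                + loadings @ factors
                + config.nuisance_leak * (nuis_weights @ nuis) / max(config.n_nuisance, 1)
                + noise
            )
            nuisance[s, :, :, sess] = nuis

    reliabilities = _expected_reliability(config, gains, node_gain, loadings).mean(axis=1)
    rts = generate_response_times(config, reliabilities, rng=rng)
    return CohortTimeCourses(
        data=data,
        config=config,
        nuisance=nuisance,
        response_times=rts,
        subject_gains=gains,
        latent_loadings=loadings,
    )


def _expected_reliability(
    config: CohortConfig,
    gains: np.ndarray,
    node_gain: np.ndarray,
    loadings: np.ndarray,
) -> np.ndarray:
    """Closed-form expected test-retest reliability per subject x node.

    With task signal A*reg, session-specific latent/nuisance/noise variance V,
    and regressor test-retest correlation ~1, the expected reliability is
    A^2 var(reg) / (A^2 var(reg) + V).
    """
    reg = generate_task_regressor(config)
    var_reg = reg.var()
    amp2 = (gains[:, None] * node_gain[None, :]) ** 2 * var_reg
    noise_var = (
        config.noise_sigma**2 / (1.0 - config.ar1_phi**2)
        if abs(config.ar1_phi) < 1
        else config.noise_sigma**2
    )
    v = (loadings**2).sum(axis=1) + noise_var
    return amp2 / (amp2 + v[None, :])


def generate_response_times(
    config: CohortConfig,
    subject_reliabilities: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-subject 48-item response times for two sessions.

    Stroop items (odd 1-based positions) are systematically faster than
    memory items (even positions).  Each subject's test-retest RT reliability
    is drawn around a latent trait correlated with the subject's time-course
    reliability at strength ``config.rt_coupling``; session noise is then
    scaled to realize that target reliability in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rel = np.asarray(subject_reliabilities, dtype=float)
    if rel.shape != (config.n_subjects,):
        raise ValueError("need one reliability scalar per subject")
    c = config.rt_coupling

    u = rel - rel.mean()
    sd = u.std()
    u = u / sd if sd > 0 else np.zeros_like(u)
    eps = rng.normal(0.0, 1.0, config.n_subjects)
    trait = c * u + np.sqrt(max(0.0, 1.0 - c**2)) * eps
    # realistic spread: mean ~0.32, sd ~0.22, clipped away from 0 and 1
    target_rel = np.clip(0.32 + 0.22 * trait, 0.02, 0.92)

    items = np.arange(N_RT_ITEMS)
    base = np.where(items % 2 == 0, 0.60, 0.72)  # position 1 (index 0) = Stroop
    base = base + rng.normal(0.0, 0.03, N_RT_ITEMS)  # stable item idiosyncrasy

    # subject-specific stable item deviations dominate the shared profile, so
    # a subject's RT reliability reflects that subject, not the task template
    rts = np.empty((config.n_subjects, N_RT_ITEMS, 2))
    for s in range(config.n_subjects):
        stable = base + rng.normal(0.0, 0.12, N_RT_ITEMS)
        sig = stable.var()
        noise_sd = np.sqrt(sig * (1.0 - target_rel[s]) / target_rel[s])
        for sess in range(2):
            rts[s, :, sess] = stable + rng.normal(0.0, noise_sd, N_RT_ITEMS)
    return rts
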