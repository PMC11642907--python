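"""Within-subject reliability, observed and detectable connectivity.

The correlation between two measured series cannot exceed the geometric mean
of their test-retest reliabilities (Nunnally's attenuation bound):

    upper_bound(A, B) = sqrt(rho_A * rho_B).

Observed connectivity (per-subject Pearson correlation between two node time
courses within a session) is therefore capped at this bound to yield the
*detectable* connectivity; negative node reliability makes the bound
undefined and zeroes the path.  Confidence intervals come from the joint
stationary block bootstrap; distribution summaries use Fisher-z averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .blockboot import BootstrapPlan, _index_matrix, _rowwise_pearson, joint_block_length
from .preprocess import prewhiten_pair

__all__ = [
    "ReliabilityTable",
    "ConnectivityTensor",
    "DistributionSummary",
    "fisher_z",
    "fisher_z_inverse",
    "fisher_mean",
    "lower_triangle_paths",
    "within_subject_reliability",
    "observed_connectivity",
    "connectivity_upper_bound",
    "detectable_connectivity",
    "detectable_connectivity_tensor",
    "absolute_mean_with_ci",
    "conventional_group_reliability",
]

Variant = Literal["observed", "ar1", "detectable", "detectable_ar1"]
_Z_CLIP = 0.999999
TEST, RETEST = 0, 1


def fisher_z(r):
    """Fisher forward transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    flat = np.atleast_1d(r)
    if np.any(np.abs(flat[np.isfinite(flat)]) >= 1):
        raise ValueError("fisher_z requires |r| < 1 (clip exact +/-1 to +/-0.999999)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z):
    """Back transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _clip_r(r):
    return np.clip(r, -_Z_CLIP, _Z_CLIP)


def fisher_mean(r: np.ndarray, axis=None):
    """Mean of correlations through the Fisher z domain (NaNs excluded)."""
    z = np.arctanh(_clip_r(np.asarray(r, dtype=float)))
    with np.errstate(invalid="ignore"):
        m = np.nanmean(z, axis=axis)
    out = np.tanh(m)
    return float(out) if np.ndim(out) == 0 else out


def variance_explained(r):
    """Fraction of variance a correlation accounts for: r squared.

    A detectable connectivity of 0.09 therefore explains 0.0081 (0.81%) of
    the signal variance.
    """
    out = np.square(np.asarray(r, dtype=float))
    return float(out) if out.ndim == 0 else out


def lower_triangle_paths(n_nodes: int) -> list[tuple[int, int]]:
    """Paths (i, j) with i > j from the lower triangle of the node matrix."""
    return [(i, j) for i in range(n_nodes) for j in range(i)]


@dataclass
class ReliabilityTable:
    """Test-retest reliability per subject x node with bootstrap CI bounds."""

    rho: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    variant: Literal["raw", "ar1"] = "raw"

    def __post_init__(self) -> None:
        fin = np.isfinite(self.rho)
        if np.any(np.abs(self.rho[fin]) > 1):
            raise ValueError("reliability outside [-1, 1]")
        both = np.isfinite(self.lo) & np.isfinite(self.hi)
        if np.any(self.lo[both] > self.hi[both]):
            raise ValueError("lo > hi in reliability CIs")

    @property
    def n_entries(self) -> int:
        return self.rho.size

    def negative_fraction(self) -> float:
        fin = np.isfinite(self.rho)
        return float((self.rho[fin] < 0).mean())


@dataclass
class ConnectivityTensor:
    """Per-subject path correlations for one session and variant.

    ``r``, ``lo``, ``hi`` are [subject, path]; ``path_index`` maps the path
    axis to lower-triangle node pairs (i, j), i > j.
    """

    r: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    session: int
    variant: Variant
    path_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.r.shape[1] != len(self.path_index):
            raise ValueError("path axis does not match path_index")

    @property
    def n_paths(self) -> int:
        return len(self.path_index)


@dataclass
class DistributionSummary:
    """Grand-mean connectivity with averaged CI bounds and distribution shape."""

    mean_r: float
    mean_lo: float
    mean_hi: float
    pct_2_5: float
    pct_97_5: float
    std: float
    std_ci: tuple[float, float]
    mean_ci: tuple[float, float]
    pct_negative: float
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if not (self.pct_2_5 <= self.mean_r <= self.pct_97_5):
            raise ValueError("mean outside its own distribution percentiles")
        if self.std < 0:
            raise ValueError("negative std")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(_rowwise_pearson(x[None, :], y[None, :])[0])


def _pair_ci(
    x: np.ndarray, y: np.ndarray, plan: BootstrapPlan, rng: np.random.Generator
) -> tuple[float, float]:
    """Joint stationary-bootstrap percentile CI for corr(x, y)."""
    b = plan.b if plan.b is not None else joint_block_length([x, y])
    idx = _index_matrix(x.size, b, plan.n_boot, rng)
    reps = _rowwise_pearson(x[idx], y[idx])
    reps = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def within_subject_reliability(
    cohort, ar1: bool = False, plan: BootstrapPlan | None = None
) -> ReliabilityTable:
    """Pearson correlation between the test and retest series of every
    subject x node, optionally after pairwise AR(1) prewhitening.

    With a :class:`BootstrapPlan`, joint block-bootstrap CIs are attached;
    otherwise CI bounds are NaN.  Constant series yield NaN (undefined).
    """
    S, N = cohort.n_subjects, cohort.n_nodes
    rho = np.full((S, N), np.nan)
    lo = np.full((S, N), np.nan)
    hi = np.full((S, N), np.nan)
    rng = np.random.default_rng(plan.seed) if plan is not None else None
    for s in range(S):
        for n in range(N):
            x = cohort.data[s, n, :, TEST]
            y = cohort.data[s, n, :, RETEST]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if ar1:
                x, y, _ = prewhiten_pair(x, y)
            rho[s, n] = _pearson(x, y)
            if plan is not None:
                lo[s, n], hi[s, n] = _pair_ci(x, y, plan, rng)
    return ReliabilityTable(rho=rho, lo=lo, hi=hi, variant="ar1" if ar1 else "raw")


def observed_connectivity(
    cohort, session: int, ar1: bool = False, plan: BootstrapPlan | None = None
) -> ConnectivityTensor:
    """Per-subject Pearson correlation of every lower-triangle node pair
    within one session (optionally pairwise AR(1)-prewhitened)."""
    if session not in (TEST, RETEST):
        raise ValueError(f"session must be 0 (test) or 1 (retest), got {session}")
    S, N = cohort.n_subjects, cohort.n_nodes
    paths = lower_triangle_paths(N)
    P = len(paths)
    r = np.full((S, P), np.nan)
    lo = np.full((S, P), np.nan)
    hi = np.full((S, P), np.nan)
    rng = np.random.default_rng(plan.seed) if plan is not None else None
    for s in range(S):
        for p, (i, j) in enumerate(paths):
            x = cohort.data[s, i, :, session]
            y = cohort.data[s, j, :, session]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if ar1:
                x, y, _ = prewhiten_pair(x, y)
            r[s, p] = _pearson(x, y)
            if plan is not None:
                lo[s, p], hi[s, p] = _pair_ci(x, y, plan, rng)
    return ConnectivityTensor(
        r=r, lo=lo, hi=hi, session=session,
        variant="ar1" if ar1 else "observed", path_index=paths,
    )


def connectivity_upper_bound(rho_a, rho_b):
    """Attenuation bound sqrt(rho_A * rho_B); negative reliabilities enter
    as zero (the root of a negative product is undefined)."""
    a = np.maximum(np.asarray(rho_a, dtype=float), 0.0)
    b = np.maximum(np.asarray(rho_b, dtype=float), 0.0)
    out = np.sqrt(a * b)
    return float(out) if out.ndim == 0 else out


def detectable_connectivity(obs_r, rho_a, rho_b):
    """Cap observed connectivity at the attenuation bound.

    Case rule: negative reliability on either node zeroes the path; otherwise
    the magnitude is min(|observed|, bound) and the sign of the observed
    correlation is kept.
    """
    obs = np.asarray(obs_r, dtype=float)
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    ub = connectivity_upper_bound(a, b)
    capped = np.sign(obs) * np.minimum(np.abs(obs), ub)
    out = np.where((a < 0) | (b < 0), 0.0, capped)
    out = np.where(np.isnan(obs) | np.isnan(a) | np.isnan(b), np.nan, out)
    return float(out) if out.ndim == 0 else out


def detectable_connectivity_tensor(
    cohort,
    session: int,
    ar1: bool = False,
    plan: BootstrapPlan | None = None,
) -> ConnectivityTensor:
    """Detectable connectivity per subject x path with bootstrap CIs.

    For each path (A, B) the observed correlation (within-session) and the two
    node reliabilities (test vs retest) are computed — each pair optionally
    prewhitened with its own AR(1) weight — and the case rule applied.  The
    CI resamples the underlying series with ONE joint index vector per
    replicate (block length = the largest of the per-series automatic
    lengths) and recomputes observed r, both reliabilities and the case rule
    per replicate.
    """
    if session not in (TEST, RETEST):
        raise ValueError(f"session must be 0 (test) or 1 (retest), got {session}")
    S, N = cohort.n_subjects, cohort.n_nodes
    paths = lower_triangle_paths(N)
    P = len(paths)
    r = np.full((S, P), np.nan)
    lo = np.full((S, P), np.nan)
    hi = np.full((S, P), np.nan)
    rng = np.random.default_rng(plan.seed) if plan is not None else None

    for s in range(S):
        # reliability pairs per node, whitened once per subject
        rel_pairs: list[tuple[np.ndarray, np.ndarray] | None] = []
        rel = np.full(N, np.nan)
        for n in range(N):
            x = cohort.data[s, n, :, TEST]
            y = cohort.data[s, n, :, RETEST]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rel_pairs.append(None)
                continue
            if ar1:
                x, y, _ = prewhiten_pair(x, y)
            rel_pairs.append((x, y))
            rel[n] = _pearson(x, y)
        for p, (i, j) in enumerate(paths):
            xa = cohort.data[s, i, :, session]
            xb = cohort.data[s, j, :, session]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0 or rel_pairs[i] is None or rel_pairs[j] is None:
                continue
            if ar1:
                xa, xb, _ = prewhiten_pair(xa, xb)
            obs = _pearson(xa, xb)
            r[s, p] = detectable_connectivity(obs, rel[i], rel[j])
            if plan is not None:
                lo[s, p], hi[s, p] = _detectable_ci(
                    xa, xb, rel_pairs[i], rel_pairs[j], plan, rng
                )
    return ConnectivityTensor(
        r=r, lo=lo, hi=hi, session=session,
        variant="detectable_ar1" if ar1 else "detectable", path_index=paths,
    )


def _detectable_ci(xa, xb, pair_a, pair_b, plan: BootstrapPlan, rng) -> tuple[float, float]:
    """Joint bootstrap of the full case rule over all underlying series."""
    series = [xa, xb, pair_a[0], pair_a[1], pair_b[0], pair_b[1]]
    n = min(s.size for s in series)
    series = [s[:n] for s in series]  # AR(1) pairs are one sample shorter pre-alignment
    b = plan.b if plan.b is not None else joint_block_length(series)
    idx = _index_matrix(n, b, plan.n_boot, rng)
    obs = _rowwise_pearson(series[0][idx], series[1][idx])
    ra = _rowwise_pearson(series[2][idx], series[3][idx])
    rb = _rowwise_pearson(series[4][idx], series[5][idx])
    reps = detectable_connectivity(obs, ra, rb)
    reps = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def absolute_mean_with_ci(
    tensor: ConnectivityTensor, n_boot: int = 2000, seed: int = 0
) -> DistributionSummary:
    """Grand mean of a connectivity distribution with averaged CI bounds.

    A path counts as *negative* when the upper bound of its correlation CI is
    below zero; such entries (r, lo, hi) are made absolute (bounds swapped)
    before averaging, so robustly negative connectivity contributes its
    magnitude.  Means of r and of the CI bounds are taken through the Fisher
    z domain (equal series lengths make df weighting obsolete); the CI of the
    distribution mean and std uses an ordinary (non-block) bootstrap over
    entries.
    """
    r = tensor.r.ravel().copy()
    lo = tensor.lo.ravel().copy()
    hi = tensor.hi.ravel().copy()
    defined = np.isfinite(r)
    n_undef = int((~defined).sum())
    r, lo, hi = r[defined], lo[defined], hi[defined]
    if r.size == 0:
        raise ValueError("no defined connectivity entries")

    neg = np.isfinite(hi) & (hi < 0)
    r[neg] = np.abs(r[neg])
    lo[neg], hi[neg] = -hi[neg], -lo[neg]

    mean_r = fisher_mean(r)
    mean_lo = fisher_mean(lo) if np.isfinite(lo).any() else np.nan
    mean_hi = fisher_mean(hi) if np.isfinite(hi).any() else np.nan
    p025, p975 = np.percentile(r, [2.5, 97.5])
    z = np.arctanh(_clip_r(r))
    std = float(np.tanh(z.std(ddof=1)))

    rng = np.random.default_rng(seed)
    boots_mean = np.empty(n_boot)
    boots_std = np.empty(n_boot)
    for i in range(n_boot):
        zb = z[rng.integers(0, z.size, z.size)]
        boots_mean[i] = np.tanh(zb.mean())
        boots_std[i] = np.tanh(zb.std(ddof=1))
    mean_ci = tuple(np.percentile(boots_mean, [2.5, 97.5]))
    std_ci = tuple(np.percentile(boots_std, [2.5, 97.5]))

    return DistributionSummary(
        mean_r=mean_r,
        mean_lo=float(mean_lo),
        mean_hi=float(mean_hi),
        pct_2_5=float(p025),
        pct_97_5=float(p975),
        std=std,
        std_ci=(float(std_ci[0]), float(std_ci[1])),
        mean_ci=(float(mean_ci[0]), float(mean_ci[1])),
        pct_negative=float(neg.mean()),
        n_undefined=n_undef,
    )


def conventional_group_reliability(
    tensor_test: ConnectivityTensor, tensor_retest: ConnectivityTensor
) -> tuple[np.ndarray, float]:
    """Group-level path reliability: correlate each path's subject estimates
    across sessions, then Fisher-average the per-path values."""
    if tensor_test.path_index != tensor_retest.path_index:
        raise ValueError("path sets differ between sessions")
    a, b = tensor_test.r, tensor_retest.r
    if a.shape != b.shape:
        raise ValueError("subject sets differ between sessions")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    P = a.shape[1]
    out = np.full(P, np.nan)
    for p in range(P):
        x, y = a[:, p], b[:, p]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
            out[p] = _pearson(x[ok], y[ok])
    return out, fisher_mean(out)
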